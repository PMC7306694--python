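"""Cross-population / cross-species diversity-landscape comparisons.

Windowed diversity (S, or Tajima's D) is compared between populations
through pairwise Spearman rank correlations over a common window set —
either BUSCO-ortholog windows comparable across assemblies, or random
window draws forming a randomization null.  Distance decay of the
landscape correlation is tested against a genetic distance matrix with a
Mantel permutation test, and an invasive-versus-native perturbation test
asks whether interspecific landscape correlations are systematically
weaker for invasive populations.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .windows import sign_binomial_test

logger = logging.getLogger(__name__)

__all__ = [
    "extract_busco_windows",
    "diversity_wide",
    "spearman_matrix",
    "tajima_correlations",
    "randomization_null",
    "alignment_distance",
    "mantel_test",
    "compare_invasive_native_correlations",
]


def extract_busco_windows(annotations: dict, shared_only: bool = True) -> pd.DataFrame:
    """Windows spanning the first to last exon of BUSCO orthologs.

    ``annotations`` maps assembly name -> either a GFF3 path or the
    feature DataFrame produced by
    :func:`divscape.synthetic.generate_annotations`.  Orthologs whose
    exons fall on multiple contigs within one assembly are excluded (and
    logged).  With ``shared_only`` the ortholog must be present in every
    assembly.  Returns long format: ortholog, assembly, contig, start,
    end (0-based half-open).
    """
    rows = []
    for asm, ann in annotations.items():
        feats = ann if isinstance(ann, pd.DataFrame) else _read_busco_gff(ann)
        exons = feats[(feats["feature"] == "exon") & (feats["busco_id"] != "")]
        if exons.empty:  # fall back to gene spans when exons are not annotated
            exons = feats[(feats["feature"] == "gene") & (feats["busco_id"] != "")]
        for bid, grp in exons.groupby("busco_id"):
            if grp["contig"].nunique() > 1:
                logger.info("%s: BUSCO %s spans multiple contigs; excluded", asm, bid)
                continue
            rows.append({"ortholog": bid, "assembly": asm,
                         "contig": grp["contig"].iloc[0],
                         "start": int(grp["start"].min()),
                         "end": int(grp["end"].max())})
    df = pd.DataFrame(rows, columns=["ortholog", "assembly", "contig", "start", "end"])
    if shared_only and not df.empty:
        n_asm = len(annotations)
        counts = df.groupby("ortholog")["assembly"].nunique()
        keep = counts[counts == n_asm].index
        df = df[df["ortholog"].isin(keep)].reset_index(drop=True)
    return df


def _read_busco_gff(path) -> pd.DataFrame:
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True, keep_order=True,
                            merge_strategy="create_unique")
    rows = []
    for ftype in ("gene", "exon"):
        for f in db.features_of_type(ftype):
            rows.append({"contig": f.seqid, "feature": ftype, "start": f.start - 1,
                         "end": f.end, "id": f.id,
                         "busco_id": f.attributes.get("busco_id", [""])[0]})
    return pd.DataFrame(rows)


def diversity_wide(tables: dict, value: str = "S") -> pd.DataFrame:
    """Stack per-population diversity tables into a windows x populations frame."""
    cols = {}
    for pop, tab in tables.items():
        idx = pd.MultiIndex.from_frame(tab[["contig", "start"]])
        cols[pop] = pd.Series(tab[value].to_numpy(), index=idx)
    return pd.DataFrame(cols)


def spearman_matrix(wide: pd.DataFrame, min_windows: int = 10):
    """Pairwise Spearman correlation matrix with pairwise-complete windows.

    ``wide`` is windows x populations (NaN = undefined in that window);
    returns (rho DataFrame, n DataFrame of windows used per pair).  A
    constant value vector within a pair yields NaN with a warning.
    """
    pops = list(wide.columns)
    rho = pd.DataFrame(np.eye(len(pops)), index=pops, columns=pops)
    n_used = pd.DataFrame(0, index=pops, columns=pops, dtype=int)
    for i, a in enumerate(pops):
        n_used.loc[a, a] = wide[a].notna().sum()
        for b in pops[i + 1:]:
            sub = wide[[a, b]].dropna()
            n_used.loc[a, b] = n_used.loc[b, a] = len(sub)
            if len(sub) < min_windows:
                raise ValueError(f"pair ({a}, {b}): only {len(sub)} shared windows "
                                 f"(< {min_windows})")
            if sub[a].nunique() == 1 or sub[b].nunique() == 1:
                warnings.warn(f"pair ({a}, {b}): constant values; rho undefined")
                r = float("nan")
            else:
                r = stats.spearmanr(sub[a], sub[b]).statistic
            rho.loc[a, b] = rho.loc[b, a] = r
    return rho, n_used


def tajima_correlations(tables: dict, min_windows: int = 10):
    """Spearman matrix of windowed Tajima's D (undefined windows dropped pairwise)."""
    return spearman_matrix(diversity_wide(tables, value="tajima_d"), min_windows)


def randomization_null(wide: pd.DataFrame, k: int = 2714, n_iter: int = 100,
                       seed=0):
    """Null distribution of pairwise rho from random window subsets.

    Each iteration draws ``k`` windows uniformly without replacement and
    recomputes the full Spearman matrix; returns a long DataFrame
    (iteration, pop_a, pop_b, rho) and a per-pair quantile summary
    (2.5% / 50% / 97.5%).
    """
    n = len(wide)
    if k > n:
        raise ValueError(f"k={k} exceeds available windows ({n})")
    rng = np.random.default_rng(seed)
    pops = list(wide.columns)
    recs = []
    for it in range(n_iter):
        sub = wide.iloc[np.sort(rng.choice(n, size=k, replace=False))]
        rho, _ = spearman_matrix(sub, min_windows=2)
        for i, a in enumerate(pops):
            for b in pops[i + 1:]:
                recs.append({"iteration": it, "pop_a": a, "pop_b": b,
                             "rho": rho.loc[a, b]})
    null = pd.DataFrame(recs)
    q = (null.groupby(["pop_a", "pop_b"])["rho"]
             .quantile([0.025, 0.5, 0.975]).unstack())
    q.columns = ["q2.5", "median", "q97.5"]
    return null, q.reset_index()


def alignment_distance(alignment, gap_chars: str = "-.nN?") -> tuple:
    """Genetic distances from a concatenated multiple alignment.

    ``alignment`` is a FASTA path or a mapping taxon -> aligned sequence.
    For each pair, sites where either sequence carries a gap/ambiguity
    character are excluded; the distance is sqrt(1 - fraction identical)
    over the remaining sites.  Returns (distance DataFrame, raw
    proportion-different DataFrame).
    """
    if hasattr(alignment, "items"):
        seqs = {k: str(v) for k, v in alignment.items()}
    else:
        from Bio import SeqIO

        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(alignment), "fasta")}
    taxa = list(seqs)
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) != 1:
        raise ValueError("aligned sequences must all have equal length")
    arr = np.array([list(s.upper()) for s in seqs.values()])
    gap = np.isin(arr, list(gap_chars.upper()))
    dist = pd.DataFrame(0.0, index=taxa, columns=taxa)
    prop = pd.DataFrame(0.0, index=taxa, columns=taxa)
    for i in range(len(taxa)):
        for j in range(i + 1, len(taxa)):
            ok = ~(gap[i] | gap[j])
            if not ok.any():
                raise ValueError(f"no comparable sites for ({taxa[i]}, {taxa[j]})")
            p_diff = float(np.mean(arr[i, ok] != arr[j, ok]))
            d = float(np.sqrt(p_diff))  # sqrt(1 - identity)
            dist.iloc[i, j] = dist.iloc[j, i] = d
            prop.iloc[i, j] = prop.iloc[j, i] = p_diff
    return dist, prop


def _triu_values(m: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(m.shape[0], k=1)
    return m[iu]


def mantel_test(m1: pd.DataFrame, m2: pd.DataFrame, n_perm: int = 10000,
                seed=0, alternative: str = "two-sided"):
    """Spearman Mantel test between two square labelled matrices.

    The statistic is the Spearman correlation of the off-diagonal upper
    triangles; the null permutes rows and columns of ``m2``
    simultaneously.  p = (1 + #extreme) / (1 + n_perm); two-sided
    compares |r_perm| >= |r_obs|, one-sided options "greater"/"less"
    compare signed r.
    """
    if list(m1.index) != list(m1.columns) or list(m2.index) != list(m2.columns):
        raise ValueError("matrices must be square with matching row/column labels")
    if set(m1.index) != set(m2.index):
        raise ValueError("label sets differ between matrices")
    if len(m1) < 4:
        raise ValueError("Mantel test needs >= 4 taxa")
    m2 = m2.loc[m1.index, m1.index]
    a1, a2 = m1.to_numpy(dtype=float), m2.to_numpy(dtype=float)
    n = a1.shape[0]
    # rank-transform once; under row/col permutation the entry multiset is
    # preserved, so ranks permute with the entries.
    iu = np.triu_indices(n, k=1)
    r1 = np.zeros_like(a1)
    r2 = np.zeros_like(a2)
    r1[iu] = stats.rankdata(a1[iu])
    r2[iu] = stats.rankdata(a2[iu])
    r1 += r1.T
    r2 += r2.T

    def pearson(x, y):
        x = x - x.mean()
        y = y - y.mean()
        return float(x @ y / np.sqrt((x @ x) * (y @ y)))

    r_obs = pearson(r1[iu], r2[iu])
    rng = np.random.default_rng(seed)
    v1 = r1[iu]
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        rp = r2[np.ix_(p, p)][iu]
        r_perm = pearson(v1, rp)
        if alternative == "two-sided":
            count += abs(r_perm) >= abs(r_obs) - 1e-12
        elif alternative == "greater":
            count += r_perm >= r_obs - 1e-12
        elif alternative == "less":
            count += r_perm <= r_obs + 1e-12
        else:
            raise ValueError("alternative must be two-sided/greater/less")
    return r_obs, (1 + count) / (1 + n_perm)


def compare_invasive_native_correlations(rho: pd.DataFrame, status: dict):
    """Are interspecific landscape correlations weaker for invasive populations?

    ``status`` maps every label of ``rho`` to "invasive", "native" (the
    focal species' populations) or "other".  For each "other" label the
    mean rho to invasive populations is compared with the mean rho to
    native populations.  Returns a dict with the per-comparison table,
    (weaker, not_weaker) counts, an exact binomial sign test, and a 2x2
    exact test on [weaker, not-weaker] x [invasive, native] (the native
    row counts comparisons where the native mean is the weaker one).
    """
    missing = [x for x in rho.index if x not in status]
    if missing:
        raise ValueError(f"status missing for labels: {missing}")
    inv = [x for x in rho.index if status[x] == "invasive"]
    nat = [x for x in rho.index if status[x] == "native"]
    oth = [x for x in rho.index if status[x] == "other"]
    if not inv or not nat:
        raise ValueError("need >= 1 invasive and >= 1 native population")
    rows = []
    for o in oth:
        mi = float(rho.loc[inv, o].mean())
        mn = float(rho.loc[nat, o].mean())
        rows.append({"other": o, "mean_rho_invasive": mi, "mean_rho_native": mn,
                     "invasive_weaker": mi < mn})
    tab = pd.DataFrame(rows)
    k = int(tab["invasive_weaker"].sum())
    n = len(tab)
    sign_p = sign_binomial_test(k, n)
    table = np.array([[k, n - k], [n - k, k]])
    fisher_p = float(stats.fisher_exact(table)[1])
    return {"comparisons": tab, "counts": (k, n - k), "sign_test_p": sign_p,
            "fisher_2x2_p": fisher_p}
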