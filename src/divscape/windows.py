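"""Per-window diversity statistics: S, pi, Tajima's D, Hudson F_ST,
gene-proximity classification and the associated tests.

All internal coordinates are 0-based half-open; VCF (1-based) and GFF3
(1-based inclusive) are converted at the I/O boundary.  Missing haplotype
calls are coded -1; per-site statistics use the non-missing haplotype
count at that site, while the sample-size constants of Tajima's D use the
fixed number of sampled haplotypes (a documented approximation for sites
with missing data).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "GenotypeMatrix",
    "load_genotypes",
    "subsample_haplotypes",
    "make_windows",
    "window_stats",
    "hudson_fst_windows",
    "classify_gene_proximity",
    "fit_proximity_glm",
    "sign_binomial_test",
    "tajima_constants",
    "tajima_d",
]


@dataclass
class GenotypeMatrix:
    """Biallelic haplotype calls for one population on one contig set.

    ``calls`` is haplotypes x sites with entries in {0, 1, -1(missing)};
    consecutive pairs of haplotype rows belong to one diploid individual.
    """

    contig: str
    positions: np.ndarray  # 0-based site coordinates, strictly increasing
    calls: np.ndarray
    samples: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.ndim != 2 or self.calls.shape[1] != self.positions.size:
            raise ValueError("calls must be haplotypes x sites matching positions")
        if self.positions.size > 1 and not np.all(np.diff(self.positions) > 0):
            raise ValueError("positions must be strictly increasing")
        bad = ~np.isin(self.calls, (0, 1, MISSING))
        if bad.any():
            raise ValueError("calls must be 0, 1 or -1 (missing)")

    @property
    def n_hap(self) -> int:
        return self.calls.shape[0]

    @property
    def n_sites(self) -> int:
        return self.calls.shape[1]


def _read_mask(mask_path) -> dict:
    """Read a BED coverage mask; returns contig -> set-like interval arrays."""
    bed = pd.read_csv(
        mask_path, sep="\t", header=None, usecols=[0, 1, 2],
        names=["contig", "start", "end"], comment="#",
    )
    return {c: g[["start", "end"]].to_numpy() for c, g in bed.groupby("contig")}


def _masked_positions(intervals: np.ndarray, positions: np.ndarray) -> np.ndarray:
    drop = np.zeros(positions.size, dtype=bool)
    for s, e in intervals:
        drop |= (positions >= s) & (positions < e)
    return drop


def load_genotypes(vcf_paths, mask_path=None, missingness_threshold: float = 0.5):
    """Load biallelic SNPs from one or more VCFs into GenotypeMatrix objects.

    Parameters
    ----------
    vcf_paths : str | Path | Mapping[str, path]
        A single VCF (population name taken from the file stem) or a
        mapping population -> VCF path.
    mask_path : optional BED of coverage-masked intervals to exclude.
    missingness_threshold : float
        Sites with a missing-genotype fraction above this value are
        dropped (the "genotyped in fewer than two individuals" hard
        filter corresponds to 0.5 at n=4 individuals).

    Returns
    -------
    dict[str, GenotypeMatrix]  (one entry per population per contig is
    avoided by requiring single-contig VCFs from the simulator; real
    multi-contig VCFs yield one concatenated matrix with per-contig
    offsets resolved by the caller's window grid).
    """
    from cyvcf2 import VCF
    from pathlib import Path

    if not hasattr(vcf_paths, "items"):
        vcf_paths = {Path(vcf_paths).stem.replace(".vcf", ""): vcf_paths}
    masks = _read_mask(mask_path) if mask_path is not None else {}

    out = {}
    for pop, path in vcf_paths.items():
        vcf = VCF(str(path))
        positions, columns, contig = [], [], None
        n_dropped = 0
        for var in vcf:
            if not var.is_snp or len(var.ALT) != 1:
                n_dropped += 1
                continue
            if contig is None:
                contig = var.CHROM
            gts = np.array([g[:2] for g in var.genotypes], dtype=np.int16).ravel()
            gts[gts < 0] = MISSING
            miss_frac = np.mean(gts == MISSING)
            if miss_frac > missingness_threshold:
                continue
            positions.append(var.POS - 1)  # to 0-based
            columns.append(gts.astype(np.int8))
        if n_dropped:
            logger.info("%s: dropped %d non-biallelic-SNP records", pop, n_dropped)
        if not positions:
            warnings.warn(f"population {pop!r}: no sites remain after filtering")
            out[pop] = GenotypeMatrix(contig or "NA", np.zeros(0, dtype=np.int64),
                                      np.zeros((0, 0), dtype=np.int8), list(vcf.samples))
            continue
        pos = np.asarray(positions, dtype=np.int64)
        calls = np.stack(columns, axis=1)
        if contig in masks:
            keep = ~_masked_positions(masks[contig], pos)
            pos, calls = pos[keep], calls[:, keep]
        out[pop] = GenotypeMatrix(contig, pos, calls, list(vcf.samples))
    return out


def subsample_haplotypes(gm: GenotypeMatrix, n_individuals: int = 4, seed=None,
                         allow_three: bool = False) -> GenotypeMatrix:
    """Randomly sample ``n_individuals`` diploids (without replacement).

    ``allow_three`` permits n_individuals=3 for populations where only
    three individuals are available.
    """
    n_ind = gm.n_hap // 2
    if n_individuals < (3 if allow_three else 4):
        raise ValueError("n_individuals below the supported minimum")
    if n_ind < n_individuals:
        raise ValueError(
            f"population has {n_ind} individuals < requested {n_individuals}; "
            "pass allow_three=True and n_individuals=3 for 3-individual populations"
        )
    if n_ind == n_individuals:
        return gm
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(n_ind, size=n_individuals, replace=False))
    rows = np.ravel(np.column_stack((2 * chosen, 2 * chosen + 1)))
    samples = [gm.samples[i] for i in chosen] if gm.samples else []
    return GenotypeMatrix(gm.contig, gm.positions, gm.calls[rows], samples)


def make_windows(contig: str, length: int, window_size: int = 5000) -> pd.DataFrame:
    """Non-overlapping windows tiling [0, length); terminal window may be short."""
    starts = np.arange(0, length, window_size, dtype=np.int64)
    ends = np.minimum(starts + window_size, length)
    return pd.DataFrame({"contig": contig, "start": starts, "end": ends})


# ---------------------------------------------------------------------------
# Tajima's D machinery


def tajima_constants(n: int) -> dict:
    """Tajima (1989) normalizing constants for n sampled haplotypes."""
    if n < 2:
        raise ValueError("need n >= 2")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def tajima_d(S: int, pi_total: float, n: int) -> float:
    """Tajima's D from segregating sites and total mean pairwise differences.

    Returns NaN when S == 0 (undefined).
    """
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return (pi_total - S / c["a1"]) / np.sqrt(var)


def _site_summaries(calls: np.ndarray):
    """Per-site derived-allele count, non-missing count, mean pairwise diffs."""
    present = calls != MISSING
    n_s = present.sum(axis=0)
    k_s = np.where(present, calls, 0).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        # mean pairwise difference at a site = 2 p (1-p) * n/(n-1)
        p = np.where(n_s > 0, k_s / np.maximum(n_s, 1), 0.0)
        pair = np.where(n_s > 1, 2.0 * p * (1.0 - p) * n_s / np.maximum(n_s - 1, 1), 0.0)
    seg = (k_s > 0) & (k_s < n_s) & (n_s >= 2)
    return k_s, n_s, pair, seg


def window_stats(gm: GenotypeMatrix, windows: pd.DataFrame | None = None,
                 window_size: int = 5000, contig_length: int | None = None,
                 accessible: np.ndarray | None = None,
                 pi_denominator: str = "accessible",
                 population: str | None = None) -> pd.DataFrame:
    """Compute S, pi and Tajima's D in non-overlapping windows.

    S counts sites with >= 2 distinct non-missing alleles.  pi sums the
    per-site mean pairwise difference [n_s/(n_s-1)] * 2 p (1-p) and
    divides by accessible sites (default) or the nominal window length
    (``pi_denominator="nominal"``).  Tajima's D uses the fixed sampled
    haplotype count in its constants and the window's S and summed
    pairwise differences; it is NaN exactly when S == 0.
    """
    if pi_denominator not in ("accessible", "nominal"):
        raise ValueError("pi_denominator must be 'accessible' or 'nominal'")
    if windows is None:
        if contig_length is None:
            contig_length = int(gm.positions[-1]) + 1 if gm.n_sites else window_size
        windows = make_windows(gm.contig, contig_length, window_size)
    k_s, n_s, pair, seg = _site_summaries(gm.calls)

    recs = []
    for w in windows.itertuples(index=False):
        lo = np.searchsorted(gm.positions, w.start, side="left")
        hi = np.searchsorted(gm.positions, w.end, side="left")
        acc = (accessible[len(recs)] if accessible is not None
               else int(w.end - w.start))
        S = int(seg[lo:hi].sum())
        pi_total = float(pair[lo:hi][seg[lo:hi]].sum())
        denom = acc if pi_denominator == "accessible" else int(w.end - w.start)
        pi = pi_total / denom if denom > 0 else float("nan")
        recs.append({
            "population": population, "contig": w.contig, "start": int(w.start),
            "end": int(w.end), "accessible_sites": acc, "S": S, "pi": pi,
            "pi_total": pi_total, "tajima_d": tajima_d(S, pi_total, gm.n_hap),
        })
    return pd.DataFrame(recs)


def hudson_fst_windows(gm_a: GenotypeMatrix, gm_b: GenotypeMatrix,
                       windows: pd.DataFrame) -> pd.DataFrame:
    """Hudson's F_ST per window (ratio of sums of per-site components).

    Per site: numerator (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1),
    denominator p1(1-p2) + p2(1-p1); both summed within the window before
    taking the ratio.  NaN where the summed denominator is 0.
    """
    common, ia, ib = np.intersect1d(gm_a.positions, gm_b.positions,
                                    return_indices=True)
    if common.size == 0:
        warnings.warn("no shared sites between populations; F_ST undefined")

    def freqs(gm, idx):
        calls = gm.calls[:, idx]
        present = calls != MISSING
        n = present.sum(axis=0).astype(float)
        k = np.where(present, calls, 0).sum(axis=0)
        return k, n

    k1, n1 = freqs(gm_a, ia)
    k2, n2 = freqs(gm_b, ib)
    ok = (n1 >= 2) & (n2 >= 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        p1, p2 = k1 / n1, k2 / n2
        num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        den = p1 * (1 - p2) + p2 * (1 - p1)
    num = np.where(ok, num, 0.0)
    den = np.where(ok, den, 0.0)

    out = []
    for w in windows.itertuples(index=False):
        lo = np.searchsorted(common, w.start, side="left")
        hi = np.searchsorted(common, w.end, side="left")
        d = den[lo:hi].sum()
        fst = num[lo:hi].sum() / d if d > 0 else float("nan")
        out.append({"contig": w.contig, "start": int(w.start), "end": int(w.end),
                    "fst": fst, "n_sites": int(hi - lo)})
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Gene proximity


def _gene_intervals_from_gff(gff3_path) -> dict:
    """Extract gene intervals (0-based half-open) per contig from GFF3."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    by_contig: dict = {}
    for gene in db.features_of_type("gene"):
        by_contig.setdefault(gene.seqid, []).append((gene.start - 1, gene.end))
    return {c: np.array(sorted(v)) for c, v in by_contig.items()}


def classify_gene_proximity(windows: pd.DataFrame, gff3, threshold: int = 5000
                            ) -> pd.Series:
    """Label each window overlap / adjacent / distant relative to genes.

    ``gff3`` may be a GFF3 path or a precomputed dict contig -> (start,
    end) interval array (0-based half-open).  Overlap: any gene interval
    intersects the window.  Adjacent: nearest gene edge strictly within
    ``threshold`` bp of the window.  Distant otherwise (including all
    windows of contigs absent from the annotation, with a warning).
    """
    genes = gff3 if isinstance(gff3, dict) else _gene_intervals_from_gff(gff3)
    labels = []
    missing_contigs = set()
    for w in windows.itertuples(index=False):
        iv = genes.get(w.contig)
        if iv is None or len(iv) == 0:
            missing_contigs.add(w.contig)
            labels.append("distant")
            continue
        gs, ge = iv[:, 0], iv[:, 1]
        if np.any((gs < w.end) & (ge > w.start)):
            labels.append("overlap")
            continue
        gap = np.minimum(np.abs(gs - w.end), np.abs(w.start - ge)).min()
        labels.append("adjacent" if gap < threshold else "distant")
    if missing_contigs:
        warnings.warn(f"contigs absent from annotation treated as distant: "
                      f"{sorted(missing_contigs)}")
    return pd.Series(labels, index=windows.index, name="proximity")


def fit_proximity_glm(records: pd.DataFrame, invasion_status: dict | None = None,
                      mode: str = "median"):
    """Poisson GLM of S on gene-proximity class (optionally x invasion status).

    Without ``invasion_status``: log-link Poisson regression of per-window
    S on proximity, per population pooled.  With it: per-window medians of
    S across the populations of each status class are modelled with a
    proximity x status interaction (``mode="median"``, the default) or all
    raw windows are used (``mode="raw"``).  Returns a statsmodels results
    wrapper; Wald p-values via ``.pvalues``.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = records.copy()
    if df["proximity"].nunique() < 2:
        raise ValueError("need >= 2 proximity classes to fit the GLM")
    if invasion_status is None:
        return smf.glm("S ~ C(proximity)", data=df,
                       family=sm.families.Poisson()).fit()
    df["status"] = df["population"].map(invasion_status)
    if df["status"].isna().any():
        raise ValueError("invasion_status missing for some populations")
    if mode == "median":
        df = (df.groupby(["status", "contig", "start", "proximity"], as_index=False)
                ["S"].median())
    elif mode != "raw":
        raise ValueError("mode must be 'median' or 'raw'")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # medians may be non-integer
        return smf.glm("S ~ C(proximity) * C(status)", data=df,
                       family=sm.families.Poisson()).fit()


def sign_binomial_test(k: int, n: int) -> float:
    """Two-sided exact binomial test at p=0.5 by doubling the smaller tail.

    The two-sided p-value is twice the smaller of P(X <= k) and
    P(X >= k), capped at 1.
    """
    from math import comb

    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("k must be in [0, n]")
    # exact integer arithmetic at p = 1/2: tails are ratios of binomial sums
    total = 2**n
    lower = sum(comb(n, i) for i in range(0, k + 1))
    upper = sum(comb(n, i) for i in range(k, n + 1))
    return min(1.0, 2.0 * min(lower, upper) / total)
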