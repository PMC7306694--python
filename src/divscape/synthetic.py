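"""Synthetic genomic and thermal-performance data with known ground truth.

Emulates the statistical structure the downstream analyses assume:

* a shared genome-wide "landscape" of diversity — per-window log theta is
  the sum of a window effect common to all populations (SD
  ``landscape_sd``) and an independent population-specific effect (SD
  ``pop_sd``);
* bottlenecked (invasive-like) versus exponentially expanded
  (native-like) demographies, simulated per window by the single-locus
  coalescent in :mod:`divscape.coalescent`;
* an extra multiplicative theta loss in bottlenecked populations whose
  log is linear in the rank-transformed recombination rate (low
  recombination -> larger loss), with a latent-correlation knob
  ``rec_landscape_corr`` that sets how tightly loss tracks the map;
* non-overlapping gene annotations, a subset flagged as BUSCO orthologs
  shared across all simulated assemblies;
* negative-binomial progeny counts around known thermal performance
  curves at the assayed mean temperatures.

Outputs are plain-text standard formats (VCF v4.2, GFF3, TSV) plus a
``SimTruth`` record for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coalescent import DemographyModel, simulate_coalescent_window
from .tpc import TPCParams, tpc_value

__all__ = [
    "LandscapeSpec",
    "SimTruth",
    "simulate_population_genomes",
    "generate_annotations",
    "simulate_tpc_dataset",
    "default_tpc_truth",
    "write_vcf",
    "write_gff3",
    "write_recmap",
    "ASSAY_TEMPERATURES",
]

# mean temperatures of the thermal performance assay (deg C)
ASSAY_TEMPERATURES = (13.9, 16.0, 18.3, 20.5, 22.7, 24.8, 27.0, 28.9)


@dataclass(frozen=True)
class LandscapeSpec:
    """Shared-landscape specification for the window grid.

    ``rec_landscape_corr`` is the target (Gaussian-copula) correlation
    between the per-window log theta-loss in bottlenecked populations and
    the recombination-rate ranks; 0 decouples loss from the map.
    ``loss_scale`` sets the maximum log-loss (theta multiplier down to
    exp(-loss_scale) in the lowest-recombination windows).
    """

    n_windows: int = 1000
    window_size: int = 5000
    log_theta_mean: float = float(np.log(10.0))
    landscape_sd: float = 0.5
    pop_sd: float = 0.1
    rec_landscape_corr: float = 0.9
    loss_scale: float = 0.8
    baseline_rec_corr: float = 0.4  # rec-aligned share of the common landscape

    def __post_init__(self) -> None:
        if self.n_windows < 1 or self.window_size < 1:
            raise ValueError("n_windows and window_size must be positive")
        if self.landscape_sd < 0 or self.pop_sd < 0:
            raise ValueError("landscape_sd and pop_sd must be non-negative")
        if abs(self.rec_landscape_corr) > 1:
            raise ValueError("|rec_landscape_corr| must be <= 1")


@dataclass
class SimTruth:
    """Generator ground truth for recovery tests."""

    spec: LandscapeSpec
    populations: list
    invasion_status: dict
    demography_by_pop: dict
    theta_by_window_by_pop: pd.DataFrame  # windows x populations
    rec_rate_by_window: np.ndarray
    gene_intervals: dict = field(default_factory=dict)
    tpc_params_by_pop: dict = field(default_factory=dict)


def _rank_uniform(x: np.ndarray) -> np.ndarray:
    """Ranks mapped to (0, 1)."""
    return stats.rankdata(x) / (len(x) + 1.0)


def simulate_population_genomes(spec: LandscapeSpec, pops, seed,
                                n_hap: int = 8, out_dir=None,
                                contig: str = "arm_1"):
    """Simulate per-population genotype matrices over a shared window grid.

    Parameters
    ----------
    pops : sequence of (name, invasion_status, DemographyModel)
        ``invasion_status`` in {"invasive", "native"}; bottleneck-style
        extra theta loss applies to populations whose demography kind is
        ``bottleneck``.
    out_dir : optional path; when given, one VCF per population plus the
        recombination map and truth tables are written there.

    Returns
    -------
    (matrices, truth) where matrices maps population ->
    :class:`~divscape.windows.GenotypeMatrix` spanning the whole contig.
    """
    from .windows import GenotypeMatrix

    pops = list(pops)
    if len(pops) < 2:
        raise ValueError("need >= 2 populations")
    rng = np.random.default_rng(seed)
    n_w, w = spec.n_windows, spec.window_size

    # recombination map: lognormal window means (2Nr per bp)
    rec = rng.lognormal(mean=np.log(0.01), sigma=0.8, size=n_w)
    u = _rank_uniform(rec)                      # rank-percentile of rec rate
    u_std = stats.norm.ppf(u)                   # standardized ranks

    # shared landscape: a recombination-aligned component (linked selection
    # depresses diversity most where recombination is low, in every
    # population) plus free landscape noise
    c = spec.baseline_rec_corr
    shared = spec.landscape_sd * (c * u_std
                                  + np.sqrt(max(1.0 - c**2, 0.0))
                                  * rng.standard_normal(n_w))
    rho = spec.rec_landscape_corr
    theta_cols = {}
    for name, status, demog in pops:
        pop_eff = rng.normal(0.0, spec.pop_sd, size=n_w)
        log_theta = spec.log_theta_mean + shared + pop_eff
        if demog.kind == "bottleneck":
            # latent correlated with rec ranks; low rec -> large loss
            z = rho * u_std + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n_w)
            loss = spec.loss_scale * (1.0 - _rank_uniform(z))
            log_theta = log_theta - loss
        theta_cols[name] = np.exp(log_theta)
    theta = pd.DataFrame(theta_cols)

    matrices = {}
    for name, status, demog in pops:
        pos_all, hap_cols = [], []
        for j in range(n_w):
            g, p = simulate_coalescent_window(n_hap, theta[name].iloc[j],
                                              demog, rng, window_size=w)
            pos_all.append(p + j * w)
            hap_cols.append(g)
        positions = np.concatenate(pos_all)
        calls = np.concatenate(hap_cols, axis=1) if hap_cols else np.zeros((n_hap, 0), np.int8)
        order = np.argsort(positions, kind="stable")
        samples = [f"{name}_ind{i}" for i in range(n_hap // 2)]
        matrices[name] = GenotypeMatrix(contig, positions[order], calls[:, order],
                                        samples)

    truth = SimTruth(
        spec=spec, populations=[p[0] for p in pops],
        invasion_status={p[0]: p[1] for p in pops},
        demography_by_pop={p[0]: p[2] for p in pops},
        theta_by_window_by_pop=theta, rec_rate_by_window=rec,
    )

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, gm in matrices.items():
            write_vcf(gm, out_dir / f"{name}.vcf", contig_length=n_w * w)
        write_recmap(truth, out_dir / "recmap.tsv", contig=contig)
        theta.assign(window=np.arange(n_w)).to_csv(
            out_dir / "theta_truth.tsv", sep="\t", index=False)
    return matrices, truth


def generate_annotations(spec: LandscapeSpec, gene_fraction: float, seed,
                         busco_fraction: float = 0.5, n_assemblies: int = 1,
                         contig: str = "arm_1", gene_len_range=(1500, 4000),
                         n_exons: int = 3):
    """Non-overlapping gene intervals on the simulated contig.

    A fraction ``gene_fraction`` of windows receives one gene placed
    fully inside the window; a fraction ``busco_fraction`` of the genes
    are flagged as BUSCO orthologs shared across all ``n_assemblies``
    simulated assemblies, with ``n_exons`` exon sub-features.  Returns a
    DataFrame of features (0-based half-open) usable directly or via
    :func:`write_gff3`.
    """
    if not 0.0 <= gene_fraction <= 1.0:
        raise ValueError("gene_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n_w, w = spec.n_windows, spec.window_size
    with_gene = rng.random(n_w) < gene_fraction
    rows = []
    gene_i = 0
    for j in np.flatnonzero(with_gene):
        glen = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        glen = min(glen, w - 2)
        start = j * w + int(rng.integers(0, w - glen))
        busco = rng.random() < busco_fraction
        gid = f"gene{gene_i:05d}"
        bid = f"BUSCO{gene_i:05d}" if busco else ""
        rows.append({"contig": contig, "feature": "gene", "start": start,
                     "end": start + glen, "id": gid, "busco_id": bid,
                     "window": j})
        bounds = np.sort(rng.choice(np.arange(1, glen), size=2 * (n_exons - 1),
                                    replace=False)) if glen > 2 * n_exons else []
        cuts = [0, *bounds, glen]
        for e in range(n_exons if len(cuts) >= 2 * n_exons else 1):
            es, ee = cuts[2 * e], cuts[min(2 * e + 1, len(cuts) - 1)]
            if ee <= es:
                continue
            rows.append({"contig": contig, "feature": "exon",
                         "start": start + es, "end": start + ee,
                         "id": f"{gid}.e{e}", "busco_id": bid, "window": j,
                         "parent": gid})
        gene_i += 1
    return pd.DataFrame(rows, columns=["contig", "feature", "start", "end",
                                       "id", "busco_id", "window", "parent"])


def simulate_divergence_decay(n_taxa: int = 7, n_windows: int = 400, seed=0,
                              drift_rate: float = 0.3, div_scale: float = 0.02,
                              theta: float = 20.0, n_hap: int = 8,
                              landscape_sd: float = 0.6, seq_length: int = 2000):
    """Multi-species scenario where landscape similarity decays with divergence.

    Taxon i diverges t_i = (i + 1) time units from a common reference.  Its
    log-theta landscape is the shared base field plus Brownian drift of
    variance ``drift_rate * t_i`` per window, so between-taxon landscape
    correlation decreases with total divergence.  A concatenated ortholog
    alignment is generated alongside by mutating a root sequence with
    per-site probability ``div_scale * t_i``, so sequence distance grows
    with the same t.  Returns (windowed S tables per taxon, alignment
    dict taxon -> sequence, divergence times).
    """
    from .windows import GenotypeMatrix, make_windows, window_stats

    rng = np.random.default_rng(seed)
    t = np.arange(1, n_taxa + 1, dtype=float)
    base = rng.normal(0.0, landscape_sd, size=n_windows)
    demog = DemographyModel()
    tables = {}
    w = 5000
    grid = make_windows("arm_1", n_windows * w, w)
    for i in range(n_taxa):
        drift = np.sqrt(drift_rate * t[i]) * rng.standard_normal(n_windows)
        # cap theta so the infinite-sites assumption (<< 1 SNP/bp) holds
        th = np.clip(np.exp(np.log(theta) + base + drift), 0.0, 400.0)
        pos_all, cols = [], []
        for j in range(n_windows):
            g, p = simulate_coalescent_window(n_hap, th[j], demog, rng,
                                              window_size=w)
            pos_all.append(p + j * w)
            cols.append(g)
        gm = GenotypeMatrix("arm_1", np.concatenate(pos_all),
                            np.concatenate(cols, axis=1))
        tables[f"taxon{i}"] = window_stats(gm, grid, population=f"taxon{i}")

    bases = np.array(list("ACGT"))
    root = rng.integers(0, 4, size=seq_length)
    seqs = {}
    for i in range(n_taxa):
        q = min(div_scale * t[i], 0.7)
        mut = rng.random(seq_length) < q
        shift = rng.integers(1, 4, size=seq_length)
        seq = np.where(mut, (root + shift) % 4, root)
        seqs[f"taxon{i}"] = "".join(bases[seq])
    return tables, seqs, t


def default_tpc_truth(populations, seed, n_shared_groups: int | None = None):
    """Draw plausible fruit-fly TPC truths, optionally with shared groups.

    With ``n_shared_groups`` set, populations are assigned round-robin to
    that many parameter sets, so some pairs of populations share exactly
    the same true curve (useful for false-difference calibration).
    """
    rng = np.random.default_rng(seed)
    groups = n_shared_groups or len(populations)
    params = []
    for _ in range(groups):
        t_min = rng.normal(9.0, 1.2)
        t_max = t_min + rng.normal(23.0, 1.5)
        params.append(TPCParams(
            stretch=float(rng.lognormal(np.log(60.0), 0.25)),
            shape_a=float(1.0 + rng.lognormal(np.log(1.6), 0.25)),
            shape_b=float(1.0 + rng.lognormal(np.log(1.2), 0.25)),
            t_min=float(t_min), t_max=float(t_max)))
    return {pop: params[i % groups] for i, pop in enumerate(populations)}


def simulate_tpc_dataset(params_by_pop: dict, temperatures=ASSAY_TEMPERATURES,
                         n_pairs: int = 12, dispersion: float = 5.0, seed=0):
    """Negative-binomial progeny counts around known curves.

    One row per (population, temperature, replicate pair): count drawn
    from NB with mean ``tpc_value(params, T)`` and size ``dispersion``
    (variance mu + mu^2/dispersion); the mean is exactly 0 outside
    [t_min, t_max], where counts are 0.  Deterministic given seed.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    rng = np.random.default_rng(seed)
    rows = []
    for pop in sorted(params_by_pop):
        par = params_by_pop[pop]
        for T in temperatures:
            mu = tpc_value(par, T)
            if mu <= 0:
                counts = np.zeros(n_pairs, dtype=int)
            else:
                p = dispersion / (dispersion + mu)
                counts = rng.negative_binomial(dispersion, p, size=n_pairs)
            for r, c in enumerate(counts):
                rows.append({"population": pop, "pair": f"{pop}_T{T}_r{r}",
                             "temperature": float(T), "count": int(c)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# writers


def write_vcf(gm, path, contig_length: int | None = None) -> None:
    """Write a GenotypeMatrix as VCF v4.2 with unphased diploid GTs.

    Consecutive haplotype rows are paired into individuals; ALT/REF are
    arbitrary A/T since only biallelic 0/1 structure matters downstream.
    """
    n_ind = gm.n_hap // 2
    samples = gm.samples or [f"ind{i}" for i in range(n_ind)]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        clen = contig_length or (int(gm.positions[-1]) + 1 if gm.n_sites else 1)
        fh.write(f"##contig=<ID={gm.contig},length={clen}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        for s in range(gm.n_sites):
            col = gm.calls[:, s]
            gts = []
            for i in range(n_ind):
                a, b = col[2 * i], col[2 * i + 1]
                gts.append(f"{'.' if a < 0 else a}/{'.' if b < 0 else b}")
            fh.write(f"{gm.contig}\t{gm.positions[s] + 1}\t.\tA\tT\t.\tPASS\t.\tGT\t"
                     + "\t".join(gts) + "\n")


def write_gff3(features: pd.DataFrame, path) -> None:
    """Write the annotation table from :func:`generate_annotations` as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in features.itertuples(index=False):
            if r.feature == "gene":
                attrs = f"ID={r.id}"
                if r.busco_id:
                    attrs += f";busco_id={r.busco_id}"
            else:
                attrs = f"ID={r.id};Parent={r.parent}"
                if r.busco_id:
                    attrs += f";busco_id={r.busco_id}"
            fh.write(f"{r.contig}\tsim\t{r.feature}\t{r.start + 1}\t{r.end}\t."
                     f"\t+\t.\t{attrs}\n")


def write_recmap(truth: SimTruth, path, contig: str = "arm_1") -> None:
    """Tab-separated window recombination map (contig, start, end, mean_rho)."""
    w = truth.spec.window_size
    n = truth.spec.n_windows
    pd.DataFrame({
        "contig": contig,
        "window_start": np.arange(n) * w,
        "window_end": np.arange(1, n + 1) * w,
        "mean_rho": truth.rec_rate_by_window,
    }).to_csv(path, sep="\t", index=False)
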