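"""Synthetic methylome generator with local and global feedback structure.

The generator produces per-genotype "true" methylation proportions for a
synthetic genome of genes and TE genes, then emits observable WGBS-style
count files (Bismark CX reports) plus truth tables, so every analysis stage
in this package can be validated against a known generative model with no
external data.

The generative model (the package's own construction — the biological
observations it emulates state phenomena, not equations):

* Wild-type layer: TE genes carry high mCG (~0.85) and appreciable mCH
  (mCHG ~0.3, mCHH ~0.1); ~20% of genes are gene-body-methylated (gbM,
  mCG ~0.4, no mCH); the rest are essentially unmethylated. A small
  fraction of "genes" get TE-like methylation, emulating mis-annotated TEs.
* met1 layer: each region's mCG is multiplied by a heritable retention
  factor r — a small fraction of regions lose mCG entirely, the rest retain
  a Beta-distributed partial level. r is drawn once per lineage and reused
  by every derived genotype.
* Establishment (F1/mF1): recovered mCH = WT mCH x E(m) x G, where m is the
  region's current absolute mCG, E is a hard-gated linear ramp
  (E = 0 below the gate c_min, rising to 1 at m_sat) and G is the global
  gain. The hard gate encodes "no residual mCG, no establishment"; the ramp
  makes graded residual mCG produce graded recovery.
* Global gain: G = (M_ref / M_genome)^gamma, with M_genome the
  length-weighted mean true mCG over annotated regions and M_ref the same
  quantity in the reference (wild-type) genome. gamma > 0 makes mCH
  targeting per unit mCG intensify in globally hypomethylated genomes —
  the negative-feedback phenomenon; gamma = 0 switches it off.
* ibm1 layer (histone-demethylase loss): genic mCH accumulates toward
  A x drive(mCG) with saturating generation kinetics 1 - exp(-t/tau),
  scaled by G; TE mCH is depleted in proportion to the genome's mean genic
  mCHG (coupling beta) — the gene/TE trade-off.
* Observation model: per-cytosine coverage ~ Poisson(lambda); methylated
  counts ~ Binomial(cov, p_obs) with p_obs folding in bisulfite
  non-conversion (false methylation) and over-conversion errors.

Scenarios bundle these layers into named experiments (``met1_f1``,
``no_feedback``, ``ibm1_course``, ``mi_siblings``, ``ddm1_ibm1``,
``global_scale_pair``). Everything is deterministic given (spec, params,
seed); per-sample streams are sub-seeded by hashing the sample label.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .io import CONTEXTS, CX_COLUMNS

__all__ = [
    "GenomeSpec",
    "FeedbackParams",
    "SyntheticGenome",
    "ScenarioResult",
    "SCENARIOS",
    "build_genome",
    "assign_wildtype_truth",
    "apply_genotype",
    "genome_mean_mcg",
    "global_gain",
    "establishment_efficiency",
    "emit_reads",
    "emit_expression",
    "simulate_scenario",
    "simulate_count_table",
    "write_scenario",
]


# ---------------------------------------------------------------------------
# specifications


@dataclass(frozen=True)
class GenomeSpec:
    """Layout of the synthetic genome.

    Region lengths are log-normal; a configurable fraction of TE genes is
    drawn short (< 1000 bp) to exercise the heatmap length filter.
    Cytosine sites are placed uniformly at the given per-bp densities
    within regions and intergenic gaps.
    """

    n_chrom: int = 2
    n_genes: int = 2000
    n_te_genes: int = 500
    te_short_fraction: float = 0.15
    gbm_fraction: float = 0.2
    misannotated_fraction: float = 0.02
    gene_length_mu: float = 7.5  # log-bp; median ~1800 bp
    gene_length_sigma: float = 0.35
    te_length_mu: float = 7.4
    te_length_sigma: float = 0.4
    te_short_min: int = 300
    te_short_max: int = 999
    gap_mean: float = 800.0
    density_cg: float = 0.02
    density_chg: float = 0.02
    density_chh: float = 0.04

    def densities(self) -> dict[str, float]:
        return {"CG": self.density_cg, "CHG": self.density_chg, "CHH": self.density_chh}


@dataclass(frozen=True)
class FeedbackParams:
    """Parameters of the establishment and feedback model.

    ``c_min``: mCG gate below which TE-gene establishment is zero.
    ``m_sat_te``/``m_sat_gene``: mCG at which the establishment ramp
    saturates (TE and genic pathways). ``gamma``: global-gain exponent
    (0 disables the negative feedback). ``a_chg``/``a_chh``: asymptotic
    genic mCH in the ibm1 pathway. ``tau``: generation time constant of
    ibm1 accumulation; ``beta``: TE-depletion coupling to mean genic mCHG.
    ``p_full_loss``/``retention_beta``: met1 retention mixture.
    ``epi_loss_prob``: per-individual probability that a gbM gene's
    epiallele is lost in a sibling. ``jitter_sd``: log-normal sd applied to
    established mCH truth. ``feedback`` in {"full", "none"}: "none" forces
    E = 1 and G = 1 (negative-control scenario).
    """

    c_min: float = 0.05
    m_sat_te: float = 0.9
    m_sat_gene: float = 0.6
    gamma: float = 1.0
    a_chg: float = 0.3
    a_chh: float = 0.1
    tau: float = 3.0
    beta: float = 6.0
    ibm1_steady_t: float = 8.0
    p_full_loss: float = 0.08
    retention_beta: tuple[float, float] = (2.0, 1.3)
    full_loss_beta: tuple[float, float] = (1.0, 60.0)
    epi_loss_prob: float = 0.25
    epi_baseline: tuple[float, float] = (0.02, 400.0)  # (mean, concentration)
    residual_mch: float = 0.005
    ddm1_retention: float = 0.1
    jitter_sd: float = 0.1
    feedback: str = "full"
    m_ref: float | None = None  # set from the WT layer when None


# expression model for TE genes: log2 RPKM = a - b1*mCG - b2*mCHG + N(0, sd)
EXPRESSION_DEFAULTS = {"a": 4.0, "b1": 3.0, "b2": 6.0, "sd": 0.5, "gene_log2_mean": 4.0, "gene_log2_sd": 1.0}


def _sub_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic per-label generator: seed + CRC32 of the label."""
    return np.random.default_rng([int(seed) % (2**31), zlib.crc32(label.encode()) % (2**31)])


def _beta_mean_conc(rng, mean, conc, size):
    mean = np.broadcast_to(np.asarray(mean, dtype=float), (size,))
    a = np.clip(mean, 1e-4, 1 - 1e-4) * conc
    b = conc - a
    return rng.beta(a, b)


# ---------------------------------------------------------------------------
# genome construction


@dataclass
class SyntheticGenome:
    """Annotations, cytosine sites, and per-region attributes."""

    spec: GenomeSpec
    annotations: pd.DataFrame
    sites: pd.DataFrame  # chrom, pos, strand, context, region_idx (-1 = intergenic)
    attrs: pd.DataFrame  # region_id, region_class, is_gbm, is_misannotated, length


def build_genome(spec: GenomeSpec, seed: int) -> SyntheticGenome:
    """Lay out regions along chromosomes and scatter cytosine sites.

    Regions are shuffled, distributed round-robin over chromosomes, and
    placed left to right with exponential intergenic gaps and a 2.5 kb
    margin at each chromosome start (so 2 kb flank profiles rarely
    truncate). Deterministic for a fixed seed.
    """
    rng = _sub_rng(seed, "genome")
    n_short = int(round(spec.n_te_genes * spec.te_short_fraction))
    te_long = spec.n_te_genes - n_short
    gene_len = np.exp(rng.normal(spec.gene_length_mu, spec.gene_length_sigma, spec.n_genes))
    gene_len = np.clip(gene_len, 1000, None).astype(np.int64)
    te_len_long = np.exp(rng.normal(spec.te_length_mu, spec.te_length_sigma, te_long))
    te_len_long = np.clip(te_len_long, 1000, None).astype(np.int64)
    te_len_short = rng.integers(spec.te_short_min, spec.te_short_max + 1, n_short)

    ids = (
        [f"G{i:05d}" for i in range(spec.n_genes)]
        + [f"TE{i:05d}" for i in range(spec.n_te_genes)]
    )
    classes = ["gene"] * spec.n_genes + ["te_gene"] * spec.n_te_genes
    lengths = np.concatenate([gene_len, te_len_long, te_len_short])

    order = rng.permutation(len(ids))
    strands = rng.choice(["+", "-"], size=len(ids))
    chrom_of = np.arange(len(ids)) % spec.n_chrom

    rows = []
    cursor = {c: 2500 for c in range(spec.n_chrom)}
    gaps = rng.exponential(spec.gap_mean, len(ids)).astype(np.int64) + 100
    for k, oi in enumerate(order):
        c = int(chrom_of[k])
        start = cursor[c]
        end = start + int(lengths[oi])
        rows.append((ids[oi], f"Chr{c + 1}", start, end, strands[k], classes[oi]))
        cursor[c] = end + int(gaps[k])
    ann = pd.DataFrame(rows, columns=["region_id", "chrom", "start", "end", "strand", "region_class"])
    ann["length"] = ann["end"] - ann["start"]

    # gbM / mis-annotated flags on genes
    gene_mask = ann["region_class"].to_numpy() == "gene"
    n_gene = int(gene_mask.sum())
    u = rng.random(n_gene)
    is_mis = u < spec.misannotated_fraction
    is_gbm = (~is_mis) & (u < spec.misannotated_fraction + spec.gbm_fraction)
    attrs = ann[["region_id", "region_class", "length"]].copy()
    attrs["is_gbm"] = False
    attrs["is_misannotated"] = False
    attrs.loc[gene_mask, "is_gbm"] = is_gbm
    attrs.loc[gene_mask, "is_misannotated"] = is_mis

    # cytosine sites: per region and per intergenic gap, per context
    densities = spec.densities()
    site_chrom, site_pos, site_ctx, site_region = [], [], [], []

    def scatter(chrom, lo, hi, region_idx):
        span = hi - lo
        if span <= 0:
            return
        for ctx, dens in densities.items():
            n = rng.poisson(dens * span)
            if n == 0:
                continue
            pos0 = np.unique(rng.integers(lo, hi, n))
            site_chrom.append(np.full(len(pos0), chrom, dtype=object))
            site_pos.append(pos0 + 1)  # report positions are 1-based
            site_ctx.append(np.full(len(pos0), ctx, dtype=object))
            site_region.append(np.full(len(pos0), region_idx, dtype=np.int64))

    prev_end = {f"Chr{c + 1}": 0 for c in range(spec.n_chrom)}
    for i, row in enumerate(ann.itertuples(index=False)):
        scatter(row.chrom, prev_end[row.chrom], row.start, -1)
        scatter(row.chrom, row.start, row.end, i)
        prev_end[row.chrom] = row.end
    for chrom, e in prev_end.items():
        scatter(chrom, e, e + 2500, -1)  # trailing margin

    sites = pd.DataFrame(
        {
            "chrom": np.concatenate(site_chrom),
            "pos": np.concatenate(site_pos).astype(np.int64),
            "context": np.concatenate(site_ctx),
            "region_idx": np.concatenate(site_region),
        }
    )
    sites["strand"] = rng.choice(["+", "-"], size=len(sites))
    sites = sites.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return SyntheticGenome(spec=spec, annotations=ann, sites=sites, attrs=attrs)


# ---------------------------------------------------------------------------
# truth layers


def assign_wildtype_truth(genome: SyntheticGenome, seed: int) -> pd.DataFrame:
    """Wild-type true methylation proportions per region x context.

    TE genes (and mis-annotated "genes"): high mCG, moderate mCHG, low
    mCHH. gbM genes: body mCG without mCH. Other genes: near zero in every
    context. Returns a frame indexed by region_id with columns CG/CHG/CHH.
    """
    rng = _sub_rng(seed, "wildtype")
    attrs = genome.attrs
    n = len(attrs)
    te_like = (attrs["region_class"] == "te_gene") | attrs["is_misannotated"]
    te_like = te_like.to_numpy()
    gbm = attrs["is_gbm"].to_numpy()

    cg = np.where(
        te_like,
        _beta_mean_conc(rng, 0.85, 40.0, n),
        np.where(gbm, _beta_mean_conc(rng, 0.40, 40.0, n), _beta_mean_conc(rng, 0.02, 400.0, n)),
    )
    chg = np.where(
        te_like, _beta_mean_conc(rng, 0.30, 150.0, n), _beta_mean_conc(rng, 0.01, 400.0, n)
    )
    chh = np.where(
        te_like, _beta_mean_conc(rng, 0.10, 150.0, n), _beta_mean_conc(rng, 0.01, 400.0, n)
    )
    truth = pd.DataFrame(
        {"CG": cg, "CHG": chg, "CHH": chh}, index=attrs["region_id"].to_numpy()
    )
    truth.index.name = "region_id"
    return truth


def genome_mean_mcg(truth: pd.DataFrame, attrs: pd.DataFrame) -> float:
    """Length-weighted mean true mCG over annotated regions."""
    w = attrs.set_index("region_id")["length"].reindex(truth.index).to_numpy(dtype=float)
    return float(np.average(truth["CG"].to_numpy(), weights=w))


def global_gain(m_genome: float, params: FeedbackParams) -> float:
    """Global negative-feedback gain G = (M_ref / M_genome)^gamma.

    G >= 1 whenever the genome is hypomethylated relative to the reference
    and gamma >= 0. ``params.m_ref`` must be set (the WT genome mean).
    """
    if params.feedback == "none":
        return 1.0
    if params.m_ref is None:
        raise ValueError("params.m_ref unset; derive it from the wild-type layer")
    return float((params.m_ref / max(m_genome, 1e-6)) ** params.gamma)


def establishment_efficiency(mcg, params: FeedbackParams, pathway: str = "te") -> np.ndarray:
    """Establishment efficiency E(m) as a function of absolute mCG.

    TE pathway: hard zero below the gate ``c_min``, then a linear ramp to 1
    at ``m_sat_te``. Genic (ibm1) pathway: ungated ramp to 1 at
    ``m_sat_gene``. With ``feedback == "none"`` the efficiency is
    identically 1 (negative control).
    """
    m = np.asarray(mcg, dtype=float)
    if params.feedback == "none":
        return np.ones_like(m)
    if pathway == "te":
        e = np.clip((m - params.c_min) / (params.m_sat_te - params.c_min), 0.0, 1.0)
        e = np.where(m < params.c_min, 0.0, e)
    else:
        e = np.clip(m / params.m_sat_gene, 0.0, 1.0)
    return e


def _jitter(p: np.ndarray, rng, params: FeedbackParams) -> np.ndarray:
    if params.jitter_sd <= 0:
        return np.clip(p, 0.0, 1.0)
    return np.clip(p * np.exp(rng.normal(0.0, params.jitter_sd, len(p))), 0.0, 1.0)


@dataclass
class Lineage:
    """Heritable state shared by genotypes derived from one lineage.

    ``retention``: per-region met1 mCG retention factors (drawn once).
    ``epi_retention``: per-individual stochastic epiallele retention for
    sibling genotypes, keyed by individual label.
    """

    retention: pd.Series
    epi_retention: dict[str, pd.Series] = field(default_factory=dict)


def draw_met1_retention(genome: SyntheticGenome, params: FeedbackParams, seed: int) -> pd.Series:
    """Per-region met1 retention mixture: full loss with prob p_full_loss,
    otherwise Beta-distributed partial retention. Heritable: reused by every
    genotype derived from the met1 lineage."""
    rng = _sub_rng(seed, "met1-retention")
    n = len(genome.attrs)
    full = rng.random(n) < params.p_full_loss
    r = np.where(
        full,
        rng.beta(*params.full_loss_beta, n),
        rng.beta(*params.retention_beta, n),
    )
    return pd.Series(r, index=genome.attrs["region_id"].to_numpy(), name="retention")


def draw_epi_loss(
    genome: SyntheticGenome, params: FeedbackParams, seed: int, individual: str
) -> pd.Series:
    """Sibling-specific heritable mCG loss: each gbM gene independently
    loses its epiallele with prob ``epi_loss_prob``. A lost gene reverts to
    the unmethylated-gene state — its mCG is redrawn from the non-gbM
    baseline distribution, not set to zero. Returns the replacement mCG per
    region (NaN = epiallele kept)."""
    rng = _sub_rng(seed, f"epi-{individual}")
    attrs = genome.attrs
    n = len(attrs)
    lose = (rng.random(n) < params.epi_loss_prob) & attrs["is_gbm"].to_numpy()
    baseline = _beta_mean_conc(rng, params.epi_baseline[0], params.epi_baseline[1], n)
    r = np.where(lose, baseline, np.nan)
    return pd.Series(r, index=attrs["region_id"].to_numpy(), name="epi_loss")


def _mean_genic_mchg(truth: pd.DataFrame, attrs: pd.DataFrame) -> float:
    gene_ids = attrs.loc[attrs["region_class"] == "gene", "region_id"]
    return float(truth.loc[gene_ids, "CHG"].mean())


def apply_genotype(
    wt_truth: pd.DataFrame,
    genotype: str,
    genome: SyntheticGenome,
    params: FeedbackParams,
    seed: int,
    lineage: Lineage | None = None,
    generation: float | None = None,
    mcg_scale: float = 1.0,
) -> pd.DataFrame:
    """Derive a genotype's truth layer from the wild-type layer.

    Supported genotypes: ``WT``, ``met1``, ``cc``, ``sss``, ``mcc``,
    ``msss``, ``F1``, ``mF1``, ``ibm1`` (requires *generation*), ``mi``,
    ``Mi`` (sibling individual; lineage must carry its epi_retention under
    the genotype label), ``ddm1``, ``ddm1_ibm1``. *mcg_scale* rescales all
    mCG before any establishment step (used by the global-scale scenarios).
    """
    attrs = genome.attrs
    te_like = ((attrs["region_class"] == "te_gene") | attrs["is_misannotated"]).to_numpy()
    truth = wt_truth.copy()
    truth["CG"] = np.clip(truth["CG"].to_numpy() * mcg_scale, 0.0, 1.0)
    rng = _sub_rng(seed, f"genotype-{genotype}-{generation}")

    def established_te(mcg_now: np.ndarray) -> pd.DataFrame:
        out = truth.copy()
        out["CG"] = mcg_now
        m_genome = genome_mean_mcg(out, attrs)
        gain = global_gain(m_genome, params)
        e = establishment_efficiency(mcg_now, params, pathway="te")
        for ctx in ("CHG", "CHH"):
            est = wt_truth[ctx].to_numpy() * e * gain
            est = _jitter(est, rng, params)
            # establishment acts on TE-like regions; genes keep their (tiny) WT mCH
            out[ctx] = np.where(te_like, est, wt_truth[ctx].to_numpy())
        out.attrs["gain"] = gain
        return out

    def ibm1_layer(base: pd.DataFrame, t: float, recompute_gain_from: pd.DataFrame) -> pd.DataFrame:
        out = base.copy()
        m_genome = genome_mean_mcg(recompute_gain_from, attrs)
        gain = global_gain(m_genome, params)
        kinet = 1.0 - np.exp(-t / params.tau)
        drive = establishment_efficiency(base["CG"].to_numpy(), params, pathway="gene")
        gene_mask = ~te_like
        for ctx, amp in (("CHG", params.a_chg), ("CHH", params.a_chh)):
            genic = amp * drive * kinet * gain
            genic = _jitter(genic, rng, params)
            out[ctx] = np.where(gene_mask, np.maximum(base[ctx].to_numpy(), genic), base[ctx].to_numpy())
        depletion = max(0.0, 1.0 - params.beta * _mean_genic_mchg(out, attrs))
        for ctx in ("CHG", "CHH"):
            out[ctx] = np.where(te_like, base[ctx].to_numpy() * depletion, out[ctx].to_numpy())
        out.attrs["gain"] = gain
        return out

    if genotype == "WT":
        truth.attrs["gain"] = 1.0
        return truth
    if genotype in {"cc", "sss"}:
        out = truth.copy()
        out[["CHG", "CHH"]] = params.residual_mch
        out.attrs["gain"] = 1.0
        return out
    if genotype in {"met1", "mcc", "msss", "mF1", "mi"} and lineage is None:
        raise ValueError(f"genotype {genotype} needs a lineage with met1 retention factors")
    if genotype == "met1":
        out = truth.copy()
        out["CG"] = truth["CG"].to_numpy() * lineage.retention.reindex(truth.index).to_numpy()
        out.attrs["gain"] = 1.0
        return out
    if genotype in {"mcc", "msss"}:
        out = truth.copy()
        out["CG"] = truth["CG"].to_numpy() * lineage.retention.reindex(truth.index).to_numpy()
        out[["CHG", "CHH"]] = params.residual_mch
        out.attrs["gain"] = 1.0
        return out
    if genotype == "F1":
        return established_te(truth["CG"].to_numpy())
    if genotype == "mF1":
        mcg = truth["CG"].to_numpy() * lineage.retention.reindex(truth.index).to_numpy()
        return established_te(mcg)
    if genotype == "ibm1":
        if generation is None:
            raise ValueError("ibm1 needs a generation index")
        return ibm1_layer(truth, float(generation), truth)
    if genotype == "mi":
        base = truth.copy()
        base["CG"] = truth["CG"].to_numpy() * lineage.retention.reindex(truth.index).to_numpy()
        return ibm1_layer(base, params.ibm1_steady_t, base)
    if genotype.startswith("Mi"):
        if lineage is None or genotype not in lineage.epi_retention:
            raise ValueError(f"genotype {genotype} needs lineage.epi_retention[{genotype!r}]")
        base = truth.copy()
        replacement = lineage.epi_retention[genotype].reindex(truth.index).to_numpy()
        base["CG"] = np.where(np.isnan(replacement), truth["CG"].to_numpy(), replacement)
        return ibm1_layer(base, params.ibm1_steady_t, base)
    if genotype == "ddm1":
        out = truth.copy()
        for ctx in ("CG", "CHG", "CHH"):
            out[ctx] = np.where(te_like, out[ctx].to_numpy() * params.ddm1_retention, out[ctx].to_numpy())
        out.attrs["gain"] = 1.0
        return out
    if genotype == "ddm1_ibm1":
        base = truth.copy()
        for ctx in ("CG", "CHG", "CHH"):
            base[ctx] = np.where(te_like, base[ctx].to_numpy() * params.ddm1_retention, base[ctx].to_numpy())
        # gain recomputed after TE loss: the depleted genome amplifies genic gain
        return ibm1_layer(base, params.ibm1_steady_t, base)
    raise ValueError(f"unknown genotype {genotype!r}")


# ---------------------------------------------------------------------------
# observation model


def emit_reads(
    genome: SyntheticGenome,
    truth: pd.DataFrame,
    sample: str,
    seed: int,
    coverage_lambda: float = 20.0,
    epsilon_nonconv: float = 0.005,
    epsilon_overconv: float = 0.002,
    background: float = 0.01,
) -> pd.DataFrame:
    """Draw a CX-report record frame for one sample from a truth layer.

    Per cytosine: coverage ~ Poisson(lambda); methylated count ~
    Binomial(coverage, p_obs) with p_obs = p_true (1 - eps_over) +
    (1 - p_true) eps_non. Intergenic sites use the flat *background* truth.
    Each sample label gets an independent deterministic substream, so
    replicates are independent draws from the same truth.
    """
    if coverage_lambda <= 0:
        raise ValueError("coverage_lambda must be positive")
    rng = _sub_rng(seed, f"reads-{sample}")
    sites = genome.sites
    region_idx = sites["region_idx"].to_numpy()
    ctx = sites["context"].to_numpy()
    p_true = np.full(len(sites), background, dtype=float)
    region_ids = genome.annotations["region_id"].to_numpy()
    truth_mat = truth.reindex(region_ids)
    for c in CONTEXTS:
        col = truth_mat[c].to_numpy()
        mask = (ctx == c) & (region_idx >= 0)
        p_true[mask] = col[region_idx[mask]]
    p_obs = p_true * (1.0 - epsilon_overconv) + (1.0 - p_true) * epsilon_nonconv
    cov = rng.poisson(coverage_lambda, len(sites))
    meth = rng.binomial(cov, p_obs)
    return pd.DataFrame(
        {
            "chrom": sites["chrom"].to_numpy(),
            "pos": sites["pos"].to_numpy(),
            "strand": sites["strand"].to_numpy(),
            "n_meth": meth.astype(np.int64),
            "n_unmeth": (cov - meth).astype(np.int64),
            "context": ctx,
            "tri": ".",
        }
    )[CX_COLUMNS]


def emit_expression(
    truth_by_genotype: dict[str, pd.DataFrame],
    genome: SyntheticGenome,
    seed: int,
    silencing: dict | None = None,
) -> pd.DataFrame:
    """RPKM table per genotype under a methylation-silencing model.

    TE genes: log2 RPKM = a - b1*mCG - b2*mCHG + Normal(0, sd) — expression
    falls as either methylation mark is restored. Genes: log-normal
    expression independent of methylation. Long format: region_id,
    genotype, rpkm.
    """
    pars = {**EXPRESSION_DEFAULTS, **(silencing or {})}
    rng = _sub_rng(seed, "expression")
    attrs = genome.attrs
    te_mask = (attrs["region_class"] == "te_gene").to_numpy()
    ids = attrs["region_id"].to_numpy()
    frames = []
    gene_log2 = rng.normal(pars["gene_log2_mean"], pars["gene_log2_sd"], len(ids))
    for genotype, truth in truth_by_genotype.items():
        t = truth.reindex(ids)
        log2 = np.where(
            te_mask,
            pars["a"]
            - pars["b1"] * t["CG"].to_numpy()
            - pars["b2"] * t["CHG"].to_numpy()
            + rng.normal(0.0, pars["sd"], len(ids)),
            gene_log2,
        )
        frames.append(
            pd.DataFrame({"region_id": ids, "genotype": genotype, "rpkm": np.power(2.0, log2)})
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# scenarios


@dataclass
class ScenarioResult:
    """Everything one scenario produces: genome, truths, reads, expression."""

    name: str
    seed: int
    genome: SyntheticGenome
    params: FeedbackParams
    truth: dict[str, pd.DataFrame]  # genotype -> truth layer
    samples: dict[str, pd.DataFrame]  # sample label -> CX record frame
    sample_genotype: dict[str, str]
    expression: pd.DataFrame | None = None
    lineage: Lineage | None = None
    _counts_cache: dict = field(default_factory=dict, repr=False)

    def region_counts(self, sample: str) -> pd.DataFrame:
        """Per-region, per-context pooled counts for one sample (cached)."""
        from .io import aggregate_region_counts

        if sample not in self._counts_cache:
            self._counts_cache[sample] = aggregate_region_counts(
                self.samples[sample], self.genome.annotations
            )
        return self._counts_cache[sample]

    def levels(self, sample: str, context: str) -> pd.Series:
        from .io import region_levels_table

        return region_levels_table(self.region_counts(sample), context)

    def pooled_levels(self, genotype: str, context: str) -> pd.Series:
        """Count-pooled weighted levels across all replicates of a genotype."""
        reps = [s for s, g in self.sample_genotype.items() if g == genotype]
        if not reps:
            raise KeyError(f"no samples for genotype {genotype!r}")
        acc = None
        for s in reps:
            c = self.region_counts(s)
            sub = c[c["context"] == context].set_index("region_id")[["n_meth", "n_total"]]
            acc = sub if acc is None else acc + sub
        out = acc["n_meth"] / acc["n_total"]
        out.name = f"{context}:{genotype}"
        return out

    def gene_set(self) -> pd.Index:
        a = self.genome.annotations
        return pd.Index(a.loc[a["region_class"] == "gene", "region_id"])

    def te_set(self) -> pd.Index:
        a = self.genome.annotations
        return pd.Index(a.loc[a["region_class"] == "te_gene", "region_id"])

    def truth_table(self) -> pd.DataFrame:
        """Long truth table: region_id, genotype, context, p_true."""
        rows = []
        for genotype, t in self.truth.items():
            melted = t.reset_index().melt(
                id_vars="region_id", var_name="context", value_name="p_true"
            )
            melted["genotype"] = genotype
            rows.append(melted)
        return pd.concat(rows, ignore_index=True)[
            ["region_id", "genotype", "context", "p_true"]
        ]


def _finish_params(params: FeedbackParams, wt_truth, genome) -> FeedbackParams:
    if params.m_ref is None:
        params = replace(params, m_ref=genome_mean_mcg(wt_truth, genome.attrs))
    return params


def _scenario_met1_f1(seed, genome_spec, params, coverage, n_f1_reps=2, n_mf1_reps=4, with_expression=True):
    genome = build_genome(genome_spec, seed)
    wt = assign_wildtype_truth(genome, seed)
    params = _finish_params(params, wt, genome)
    lineage = Lineage(retention=draw_met1_retention(genome, params, seed))
    truth = {"WT": apply_genotype(wt, "WT", genome, params, seed)}
    for g in ("met1", "cc", "sss", "mcc", "msss", "F1", "mF1"):
        truth[g] = apply_genotype(wt, g, genome, params, seed, lineage=lineage)
    samples, sample_genotype = {}, {}
    singles = ["WT", "met1", "cc", "sss", "mcc", "msss"]
    reps = [("F1", n_f1_reps), ("mF1", n_mf1_reps)]
    for g in singles:
        samples[g] = emit_reads(genome, truth[g], g, seed, coverage)
        sample_genotype[g] = g
    for g, n in reps:
        for r in range(1, n + 1):
            label = f"{g}_rep{r}"
            samples[label] = emit_reads(genome, truth[g], label, seed, coverage)
            sample_genotype[label] = g
    expr = emit_expression(
        {g: truth[g] for g in ("WT", "met1", "mcc", "msss", "F1", "mF1")}, genome, seed
    ) if with_expression else None
    return ScenarioResult("met1_f1", seed, genome, params, truth, samples, sample_genotype, expr, lineage)


def _scenario_no_feedback(seed, genome_spec, params, coverage):
    params = replace(params, feedback="none")
    res = _scenario_met1_f1(seed, genome_spec, params, coverage, with_expression=False)
    res.name = "no_feedback"
    return res


def _scenario_ibm1_course(seed, genome_spec, params, coverage, generations=(1, 2, 3, 4)):
    genome = build_genome(genome_spec, seed)
    wt = assign_wildtype_truth(genome, seed)
    params = _finish_params(params, wt, genome)
    truth = {"WT": apply_genotype(wt, "WT", genome, params, seed)}
    for t in generations:
        truth[f"ibm1_g{t}"] = apply_genotype(wt, "ibm1", genome, params, seed, generation=t)
    samples = {g: emit_reads(genome, tr, g, seed, coverage) for g, tr in truth.items()}
    return ScenarioResult(
        "ibm1_course", seed, genome, params, truth, samples, {g: g for g in truth}
    )


def _scenario_mi_siblings(seed, genome_spec, params, coverage, n_individuals=2, include_mi=False):
    genome = build_genome(genome_spec, seed)
    wt = assign_wildtype_truth(genome, seed)
    params = _finish_params(params, wt, genome)
    lineage = Lineage(retention=draw_met1_retention(genome, params, seed))
    labels = [f"Mi_{k}" for k in range(1, n_individuals + 1)]
    for lab in labels:
        lineage.epi_retention[lab] = draw_epi_loss(genome, params, seed, lab)
    truth = {"WT": apply_genotype(wt, "WT", genome, params, seed)}
    truth["ibm1"] = apply_genotype(wt, "ibm1", genome, params, seed, generation=params.ibm1_steady_t)
    for lab in labels:
        truth[lab] = apply_genotype(wt, lab, genome, params, seed, lineage=lineage)
    if include_mi:
        truth["mi"] = apply_genotype(wt, "mi", genome, params, seed, lineage=lineage)
    samples = {g: emit_reads(genome, tr, g, seed, coverage) for g, tr in truth.items()}
    return ScenarioResult(
        "mi_siblings", seed, genome, params, truth, samples, {g: g for g in truth}, None, lineage
    )


def _scenario_ddm1_ibm1(seed, genome_spec, params, coverage):
    genome = build_genome(genome_spec, seed)
    wt = assign_wildtype_truth(genome, seed)
    params = _finish_params(params, wt, genome)
    truth = {
        "WT": apply_genotype(wt, "WT", genome, params, seed),
        "ibm1": apply_genotype(wt, "ibm1", genome, params, seed, generation=params.ibm1_steady_t),
        "ddm1": apply_genotype(wt, "ddm1", genome, params, seed),
        "ddm1_ibm1": apply_genotype(wt, "ddm1_ibm1", genome, params, seed),
    }
    samples = {g: emit_reads(genome, tr, g, seed, coverage) for g, tr in truth.items()}
    return ScenarioResult(
        "ddm1_ibm1", seed, genome, params, truth, samples, {g: g for g in truth}
    )


def _scenario_global_scale_pair(seed, genome_spec, params, coverage, scale=0.5):
    """Two ibm1-background conditions identical except genome-wide mCG scale.

    The reference condition uses the genome as drawn; the scaled condition
    multiplies every region's mCG by *scale* before the ibm1 layer. Both
    share M_ref from the unscaled wild type, so gamma = 0 makes the two
    genic dose-response curves coincide in absolute mCG while gamma > 0
    boosts the scaled (hypomethylated) genome's gain.
    """
    genome = build_genome(genome_spec, seed)
    wt = assign_wildtype_truth(genome, seed)
    params = _finish_params(params, wt, genome)
    truth = {
        "WT": apply_genotype(wt, "WT", genome, params, seed),
        "ibm1_ref": apply_genotype(wt, "ibm1", genome, params, seed, generation=params.ibm1_steady_t),
        "ibm1_scaled": apply_genotype(
            wt, "ibm1", genome, params, seed, generation=params.ibm1_steady_t, mcg_scale=scale
        ),
    }
    samples = {g: emit_reads(genome, tr, g, seed, coverage) for g, tr in truth.items()}
    return ScenarioResult(
        "global_scale_pair", seed, genome, params, truth, samples, {g: g for g in truth}
    )


SCENARIOS = {
    "met1_f1": _scenario_met1_f1,
    "no_feedback": _scenario_no_feedback,
    "ibm1_course": _scenario_ibm1_course,
    "mi_siblings": _scenario_mi_siblings,
    "ddm1_ibm1": _scenario_ddm1_ibm1,
    "global_scale_pair": _scenario_global_scale_pair,
}


def simulate_scenario(
    name: str,
    seed: int,
    genome_spec: GenomeSpec | None = None,
    params: FeedbackParams | None = None,
    coverage: float = 20.0,
    **kwargs,
) -> ScenarioResult:
    """Run a named scenario; see :data:`SCENARIOS` for the available names."""
    if name not in SCENARIOS:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return SCENARIOS[name](
        seed, genome_spec or GenomeSpec(), params or FeedbackParams(), coverage, **kwargs
    )


def simulate_count_table(
    n_regions: int,
    n_replicates: int,
    p: float | np.ndarray,
    rho: float,
    seed: int,
    total_per_replicate: float = 500.0,
) -> list[pd.DataFrame]:
    """Beta-binomial replicate count frames for test-calibration studies.

    One frame per replicate, indexed by synthetic region ids, with columns
    ``n_meth``/``n_total``. Totals ~ Poisson(total_per_replicate); per
    region and replicate the methylated count is Binomial(total, pi) with
    pi ~ Beta(p, rho) per replicate (intra-class correlation rho).
    """
    rng = np.random.default_rng(int(seed) % (2**31))
    p_arr = np.broadcast_to(np.asarray(p, dtype=float), (n_regions,))
    idx = pd.Index([f"R{i:05d}" for i in range(n_regions)], name="region_id")
    t = (1.0 - rho) / max(rho, 1e-8)
    frames = []
    for _ in range(n_replicates):
        n_total = rng.poisson(total_per_replicate, n_regions)
        if rho > 1e-8:
            pi = rng.beta(np.clip(p_arr, 1e-4, 1 - 1e-4) * t, np.clip(1 - p_arr, 1e-4, 1 - 1e-4) * t)
        else:
            pi = p_arr
        k = rng.binomial(n_total, pi)
        frames.append(pd.DataFrame({"n_meth": k, "n_total": n_total}, index=idx))
    return frames


def write_scenario(result: ScenarioResult, outdir) -> dict:
    """Write a scenario to disk: gzip CX reports, BED annotation, truth and
    expression TSVs, and a YAML config capturing all parameters. Returns the
    mapping of artifact names to paths."""
    from pathlib import Path

    import yaml

    from .io import write_annotations, write_cx_report

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    ann_path = outdir / "annotations.bed"
    write_annotations(result.genome.annotations, ann_path)
    paths["annotations"] = ann_path
    for sample, records in result.samples.items():
        p = outdir / f"{sample}.CX_report.txt.gz"
        write_cx_report(records, p)
        paths[f"sample:{sample}"] = p
    truth_path = outdir / "truth.tsv"
    result.truth_table().to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    attrs_path = outdir / "region_attrs.tsv"
    result.genome.attrs.to_csv(attrs_path, sep="\t", index=False)
    paths["region_attrs"] = attrs_path
    if result.expression is not None:
        expr_path = outdir / "expression.tsv"
        result.expression.to_csv(expr_path, sep="\t", index=False)
        paths["expression"] = expr_path
    cfg = {
        "scenario": result.name,
        "seed": result.seed,
        "genome_spec": asdict(result.genome.spec),
        "params": asdict(result.params),
        "samples": result.sample_genotype,
    }
    cfg_path = outdir / "scenario.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
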