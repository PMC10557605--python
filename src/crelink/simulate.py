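"""Synthetic barcode-matched multiome generator with planted ground truth.

Generates everything the variant-to-gene pipeline consumes — peak-by-cell and
gene-by-cell count matrices over a shared barcode set, per-cell-type peak
atlases, a GWAS locus with LD structure, TF motif scenes, footprint insertion
tracks, and reporter-assay tables — with the planted objects (peak-gene links,
co-accessible modules, cell-type-private peaks, causal variants, allelic
motifs, footprint protection, allelic reporter shifts) recorded in a
:class:`GroundTruth` object so every downstream stage can be scored against
a known answer.

Generative model
----------------
ATAC counts are a Bernoulli x Poisson mixture per peak x cell with a per-cell
depth factor: a peak is "open" in a cell with a probability set by its
detection pattern (private / category-restricted / shared), and open peaks
receive Poisson-distributed insertion counts. RNA counts are negative
binomial with cell-type-specific means. A planted peak-gene link shares a
standard-normal latent factor between the peak's Poisson log-mean and the
gene's NB log-mean, so the link is explicit and recoverable by correlation.
Planted co-accessible modules modulate the open-probability of member peaks
with a chained (AR-1 style) latent factor, giving strong co-accessibility
between nearby members.

LD blocks use a first-order Markov copying process over haplotypes; R^2 to
the lead is the squared Pearson correlation of genotype dosages, exactly as
reference-panel R^2 is used downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from ._rng import child_rng
from .taxonomy import DEFAULT_TAXONOMY, TaxonomyError, validate_taxonomy

BASES = np.array(list("ACGT"))


class ConfigError(ValueError):
    """Invalid simulation configuration."""


# ---------------------------------------------------------------------------
# configuration & containers
# ---------------------------------------------------------------------------

def _default_links() -> List[Tuple[int, int, float]]:
    # (peak index, gene index, latent loading)
    return [(10, 1, 0.5), (20, 2, 0.5), (30, 3, 0.5)]


def _default_modules() -> List[Tuple[Tuple[int, ...], float]]:
    # (member peak indices, adjacent-member latent correlation); the first
    # member of each module is a planted-link peak, so the module's activity
    # drives its target gene
    return [((10, 11, 12), 0.9), ((20, 21, 22), 0.9), ((30, 31, 32), 0.9)]


@dataclass
class SimConfig:
    """Study-design constants for the synthetic multiome.

    Defaults emulate the study conditions: 23 cell types in 4 categories
    (8 epithelial, 7 immune, 4 endothelial, 4 stromal), ~2,000 cells total,
    roughly a third of peaks private to a single cell type, planted
    peak-gene links with latent loading 0.5 inside a +/-1 Mb cis window.
    """

    n_cells_per_type: int = 87
    taxonomy: Dict[str, str] = field(default_factory=lambda: dict(DEFAULT_TAXONOMY))
    n_peaks: int = 400
    n_genes: int = 60
    frac_private_peaks: float = 0.35
    frac_category_peaks: float = 0.25
    planted_links: List[Tuple[int, int, float]] = field(default_factory=_default_links)
    planted_modules: List[Tuple[Tuple[int, ...], float]] = field(
        default_factory=_default_modules
    )
    ld_block: Tuple[int, float, int] = (50, 0.05, 0)  # (n_variants, decay/kb, lead idx)
    n_individuals: int = 500
    gwas_effect: float = 0.5
    motif_scenes: List[Tuple[str, int, str, str]] = field(
        default_factory=lambda: [("TF1", 3, None, None), ("TF2", 5, None, None)]
    )
    footprint_depletion: float = 0.4
    mpra_effect: float = 0.5
    # nuisance scales, chosen once as realistic for sparse multiome data
    peak_open_lo: float = 0.15
    peak_open_hi: float = 0.5
    atac_poisson_mean: float = 1.5
    rna_log_mean: float = np.log(2.0)
    rna_log_sd: float = 0.6
    rna_dispersion: float = 10.0
    depth_log_sd: float = 0.3
    module_latent_scale: float = 4.0
    chrom: str = "chr1"
    peak_spacing: int = 5_000
    peak_width: int = 500
    seed: int = 0

    def validate(self) -> None:
        validate_taxonomy(self.taxonomy)
        for name, v in [
            ("frac_private_peaks", self.frac_private_peaks),
            ("frac_category_peaks", self.frac_category_peaks),
            ("footprint_depletion", self.footprint_depletion),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.frac_private_peaks + self.frac_category_peaks > 1.0:
            raise ConfigError("private + category peak fractions exceed 1")
        n_var, decay, lead = self.ld_block
        if n_var < 2:
            raise ConfigError("ld_block needs at least 2 variants")
        if decay <= 0:
            raise ConfigError("LD decay rate must be positive")
        if not 0 <= lead < n_var:
            raise ConfigError("lead index outside the block")
        for peak, gene, loading in self.planted_links:
            if not 0 <= peak < self.n_peaks or not 0 <= gene < self.n_genes:
                raise ConfigError("planted link indices out of range")
        for members, strength in self.planted_modules:
            if len(members) < 2:
                raise ConfigError("planted module needs >= 2 peaks")
            if any(not 0 <= m < self.n_peaks for m in members):
                raise ConfigError("planted module peak out of range")

    # genomic layout -------------------------------------------------------
    def peak_coords(self) -> Tuple[np.ndarray, np.ndarray]:
        starts = 10_000 + np.arange(self.n_peaks) * self.peak_spacing
        return starts, starts + self.peak_width

    def gene_tss(self) -> np.ndarray:
        """TSS positions; planted-link genes sit 10 kb from their peak."""
        starts, ends = self.peak_coords()
        span = int(ends[-1]) + 50_000
        tss = np.linspace(10_000, span - 10_000, self.n_genes).astype(int)
        for peak, gene, _ in self.planted_links:
            mid = (starts[peak] + ends[peak]) // 2
            tss[gene] = int(mid) + 10_000
        return tss


@dataclass
class GroundTruth:
    """Planted objects, for scoring downstream recovery."""

    true_links: Set[Tuple[str, str]]
    true_modules: List[Set[str]]
    true_specificity: Dict[str, Tuple[str, Optional[str]]]  # peak -> (level, label)
    true_ccvs: Set[str]
    relevant_cell_type: Optional[str]
    true_allelic_tfs: Set[Tuple[str, str]]

    def to_dict(self) -> dict:
        return {
            "true_links": sorted(list(t) for t in self.true_links),
            "true_modules": [sorted(m) for m in self.true_modules],
            "true_specificity": {k: list(v) for k, v in self.true_specificity.items()},
            "true_ccvs": sorted(self.true_ccvs),
            "relevant_cell_type": self.relevant_cell_type,
            "true_allelic_tfs": sorted(list(t) for t in self.true_allelic_tfs),
        }


@dataclass
class MultiomeMatrices:
    """Barcode-matched peak x cell and gene x cell count matrices."""

    atac: np.ndarray  # peaks x cells, integer counts
    rna: np.ndarray  # genes x cells, integer counts
    barcodes: List[str]
    peaks: pd.DataFrame  # name, chrom, start, end, gc, width
    genes: pd.DataFrame  # gene, chrom, tss, strand
    cells: pd.DataFrame  # barcode, cell_type, category, sample, smoking


@dataclass
class CreAtlas:
    """Per-cell-type peak detection: which peaks are detected where."""

    peaks: pd.DataFrame  # name, chrom, start, end
    detected_in: Dict[str, Set[str]]  # peak name -> set of cell types


@dataclass
class GwasLocus:
    """One GWAS locus: summary statistics, LD to lead, genotype dosages."""

    locus_id: str
    variants: pd.DataFrame  # variant_id chrom pos ref alt p_value r2_to_lead is_lead is_conditional
    lead_id: str
    genotypes: Optional[np.ndarray] = None  # variants x individuals dosages


@dataclass
class FootprintTrack:
    """Per-site Tn5 insertion counts around motif occurrences, plus bias."""

    positions: np.ndarray  # bp relative to motif centre
    site_counts: np.ndarray  # sites x positions
    bias: np.ndarray  # expected per-position insertion propensity
    core_mask: np.ndarray  # True over the motif core


# ---------------------------------------------------------------------------
# multiome
# ---------------------------------------------------------------------------

def generate_multiome(config: SimConfig) -> Tuple[MultiomeMatrices, CreAtlas, GroundTruth]:
    """Generate barcode-matched count matrices with planted architecture."""
    config.validate()
    types = list(config.taxonomy)
    categories = sorted(set(config.taxonomy.values()))
    by_cat = {c: [t for t in types if config.taxonomy[t] == c] for c in categories}

    n_types = len(types)
    n_cells = config.n_cells_per_type * n_types
    n_peaks, n_genes = config.n_peaks, config.n_genes

    cell_type = np.repeat(np.arange(n_types), config.n_cells_per_type)
    barcodes = [f"BC{i:05d}" for i in range(n_cells)]

    rng_pattern = child_rng(config.seed, "peak-pattern")
    rng_atac = child_rng(config.seed, "atac")
    rng_rna = child_rng(config.seed, "rna")
    rng_latent = child_rng(config.seed, "latent")
    rng_meta = child_rng(config.seed, "metadata")

    # --- detection patterns: private / category / shared -------------------
    u = rng_pattern.uniform(size=n_peaks)
    pattern_kind = np.where(
        u < config.frac_private_peaks,
        0,
        np.where(u < config.frac_private_peaks + config.frac_category_peaks, 1, 2),
    )
    # planted link/module peaks are kept shared so their signal spans cells
    special = {p for p, _, _ in config.planted_links}
    special |= {m for members, _ in config.planted_modules for m in members}
    pattern_kind[list(special)] = 2

    detected = np.zeros((n_peaks, n_types), dtype=bool)
    true_specificity: Dict[str, Tuple[str, Optional[str]]] = {}
    peak_names = [f"peak{j:05d}" for j in range(n_peaks)]
    for j in range(n_peaks):
        if pattern_kind[j] == 0:
            t = int(rng_pattern.integers(n_types))
            detected[j, t] = True
            true_specificity[peak_names[j]] = ("cell_type", types[t])
        elif pattern_kind[j] == 1:
            c = categories[int(rng_pattern.integers(len(categories)))]
            for t in by_cat[c]:
                detected[j, types.index(t)] = True
            true_specificity[peak_names[j]] = ("category", c)
        else:
            detected[j, :] = True
            true_specificity[peak_names[j]] = ("shared", None)

    # --- ATAC: Bernoulli(open) x Poisson(count) ----------------------------
    base_open = rng_pattern.uniform(config.peak_open_lo, config.peak_open_hi, n_peaks)
    depth = np.exp(rng_atac.normal(0.0, config.depth_log_sd, n_cells))

    open_prob = np.where(detected[:, cell_type], base_open[:, None], 0.0)
    gate_logit = np.full((n_peaks, n_cells), -np.inf)
    nz = open_prob > 0
    gate_logit[nz] = logit(np.broadcast_to(base_open[:, None], open_prob.shape)[nz])

    # link latents: one standard-normal factor per planted link, added to the
    # gene's NB log-mean (below) and to the peak's accessibility propensity
    link_z = {}
    for peak, gene, loading in config.planted_links:
        z = rng_latent.standard_normal(n_cells)
        link_z[(peak, gene)] = (z, loading)

    # module latents: chained factors so adjacent members correlate at
    # `strength`, which yields high pairwise (and partial) co-accessibility.
    # When a module's first member is a planted-link peak, the chain's root
    # factor IS that link's latent: the module's co-activity drives the gene.
    module_names: List[Set[str]] = []
    in_module: Set[int] = set()
    root_z = {p: z for (p, _g), (z, _l) in link_z.items()}
    for members, strength in config.planted_modules:
        f = np.empty((len(members), n_cells))
        f[0] = root_z.get(members[0], rng_latent.standard_normal(n_cells))
        for k in range(1, len(members)):
            f[k] = strength * f[k - 1] + np.sqrt(1 - strength**2) * rng_latent.standard_normal(n_cells)
        for k, m in enumerate(members):
            gate_logit[m] = gate_logit[m] + config.module_latent_scale * f[k]
            in_module.add(m)
        module_names.append({peak_names[m] for m in members})

    # a link peak outside any module gets the latent on its own gate logit
    # (sparse accessibility is near-binary, so the gate carries the signal)
    for (peak, gene), (z, loading) in link_z.items():
        if peak not in in_module:
            gate_logit[peak] = gate_logit[peak] + loading * z

    gate = expit(gate_logit)
    gate = np.clip(gate * depth[None, :], 0.0, 0.98)
    is_open = rng_atac.uniform(size=gate.shape) < gate

    log_lam = np.log(config.atac_poisson_mean) + np.log(depth)[None, :]
    log_lam = np.broadcast_to(log_lam, (n_peaks, n_cells)).copy()
    for (peak, gene), (z, loading) in link_z.items():
        log_lam[peak] += loading * z
    atac = np.where(is_open, rng_atac.poisson(np.exp(log_lam)), 0).astype(np.int64)
    # an "open" draw with a zero Poisson count is still a detection event
    atac[is_open & (atac == 0)] = 1
    atac[~detected[:, cell_type]] = 0  # hard zero outside detected types

    # --- RNA: negative binomial with type-specific means --------------------
    log_mu_gt = rng_rna.normal(config.rna_log_mean, config.rna_log_sd, (n_genes, n_types))
    rdepth = np.exp(rng_rna.normal(0.0, config.depth_log_sd, n_cells))
    log_mu = log_mu_gt[:, cell_type] + np.log(rdepth)[None, :]
    for (peak, gene), (z, loading) in link_z.items():
        log_mu[gene] += loading * z
    mu = np.exp(log_mu)
    theta = config.rna_dispersion
    rna = rng_rna.negative_binomial(theta, theta / (theta + mu)).astype(np.int64)

    # --- tables -------------------------------------------------------------
    starts, ends = config.peak_coords()
    gc = rng_pattern.uniform(0.35, 0.65, n_peaks)
    peaks = pd.DataFrame(
        {
            "name": peak_names,
            "chrom": config.chrom,
            "start": starts,
            "end": ends,
            "gc": gc,
            "width": ends - starts,
        }
    )
    gene_names = [f"gene{k:03d}" for k in range(n_genes)]
    genes = pd.DataFrame(
        {
            "gene": gene_names,
            "chrom": config.chrom,
            "tss": config.gene_tss(),
            "strand": rng_meta.choice(["+", "-"], n_genes),
        }
    )
    samples = rng_meta.choice([f"S{i}" for i in range(1, 17)], n_cells)
    smoking = rng_meta.choice(["ever", "never"], n_cells)
    cells = pd.DataFrame(
        {
            "barcode": barcodes,
            "cell_type": [types[t] for t in cell_type],
            "category": [config.taxonomy[types[t]] for t in cell_type],
            "sample": samples,
            "smoking": smoking,
        }
    )

    matrices = MultiomeMatrices(atac=atac, rna=rna, barcodes=barcodes, peaks=peaks, genes=genes, cells=cells)
    atlas = CreAtlas(
        peaks=peaks[["name", "chrom", "start", "end"]].copy(),
        detected_in={peak_names[j]: {types[t] for t in np.where(detected[j])[0]} for j in range(n_peaks)},
    )
    truth = GroundTruth(
        true_links={(peak_names[p], gene_names[g]) for p, g, _ in config.planted_links},
        true_modules=module_names,
        true_specificity=true_specificity,
        true_ccvs=set(),
        relevant_cell_type=None,
        true_allelic_tfs=set(),
    )
    return matrices, atlas, truth


# ---------------------------------------------------------------------------
# GWAS locus
# ---------------------------------------------------------------------------

def generate_gwas_locus(
    config: SimConfig,
    locus_id: str = "locus1",
    anchor_pos: Optional[int] = None,
    stream: str = "gwas",
) -> GwasLocus:
    """Simulate a haplotype block with exponentially decaying LD.

    Haplotypes follow a first-order Markov copying process: each variant's
    allele copies the previous variant's allele with probability
    exp(-decay * distance_kb), otherwise it is drawn fresh. Association
    p-values come from a phenotype with a planted effect at the lead variant;
    the phenotype noise substream is re-drawn (bounded, deterministic) until
    the lead attains the smallest p-value, so the block is a well-formed
    GWAS signal.
    """
    config.validate()
    n_var, decay, lead = config.ld_block
    n_ind = config.n_individuals
    rng = child_rng(config.seed, f"{stream}:{locus_id}")

    spacing = rng.integers(200, 1800, n_var - 1)
    pos = np.concatenate([[0], np.cumsum(spacing)])
    start = (anchor_pos - pos[lead]) if anchor_pos is not None else 1_000_000
    pos = pos + start

    freqs = rng.uniform(0.1, 0.9, n_var)
    n_hap = 2 * n_ind
    hap = np.empty((n_var, n_hap), dtype=np.int8)
    hap[0] = rng.uniform(size=n_hap) < freqs[0]
    for j in range(1, n_var):
        d_kb = (pos[j] - pos[j - 1]) / 1_000.0
        copy = rng.uniform(size=n_hap) < np.exp(-decay * d_kb)
        fresh = rng.uniform(size=n_hap) < freqs[j]
        hap[j] = np.where(copy, hap[j - 1], fresh)
    geno = (hap[:, :n_ind] + hap[:, n_ind:]).astype(np.float64)

    # monomorphic variants carry no information; give them a token frequency
    mono = geno.std(axis=1) == 0
    if mono.any():
        for j in np.where(mono)[0]:
            flip = rng.integers(n_ind)
            geno[j, flip] = 1.0

    g_lead = geno[lead]
    gl = (g_lead - g_lead.mean()) / g_lead.std()
    r = _rowwise_pearson(geno, geno[lead])
    r2 = r**2

    from scipy import stats

    for attempt in range(100):
        noise = child_rng(config.seed, f"{stream}:{locus_id}:y{attempt}").standard_normal(n_ind)
        y = config.gwas_effect * gl + noise
        ry = _rowwise_pearson(geno, y)
        tstat = ry * np.sqrt((n_ind - 2) / np.maximum(1e-300, 1 - ry**2))
        pvals = 2 * stats.t.sf(np.abs(tstat), df=n_ind - 2)
        pvals = np.clip(pvals, 1e-300, 1.0)
        if np.argmin(pvals) == lead:
            break

    ref = rng.choice(BASES, n_var)
    alt = np.array([rng.choice([b for b in BASES if b != r_]) for r_ in ref])
    variants = pd.DataFrame(
        {
            "variant_id": [f"rs{locus_id}_{j}" for j in range(n_var)],
            "chrom": config.chrom,
            "pos": pos.astype(int),
            "ref": ref,
            "alt": alt,
            "p_value": pvals,
            "r2_to_lead": r2,
            "is_lead": np.arange(n_var) == lead,
            "is_conditional": False,
        }
    )
    return GwasLocus(
        locus_id=locus_id,
        variants=variants,
        lead_id=f"rs{locus_id}_{lead}",
        genotypes=geno,
    )


def _rowwise_pearson(rows: np.ndarray, y: np.ndarray) -> np.ndarray:
    rc = rows - rows.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((rc**2).sum(axis=1) * (yc**2).sum())
    denom = np.where(denom == 0, np.inf, denom)
    return rc @ yc / denom


# ---------------------------------------------------------------------------
# footprint tracks
# ---------------------------------------------------------------------------

def generate_footprint_track(
    config: SimConfig,
    n_sites: int = 200,
    motif_len: int = 10,
    flank: int = 250,
    base_rate: float = 2.0,
    depletion: Optional[float] = None,
    stream: str = "footprint",
) -> FootprintTrack:
    """Insertion counts around motif sites, with a sequence-bias track.

    Counts at each position are Poisson with mean base_rate x bias, and the
    motif-core positions lose ``depletion`` of their signal (TF protection).
    The bias track (the expected insertion propensity from local sequence
    composition alone) is emitted alongside, as a bias-correction input.
    """
    if depletion is None:
        depletion = config.footprint_depletion
    if not 0 <= depletion <= 1:
        raise ConfigError("depletion must be in [0, 1]")
    length = 2 * flank + 1
    if length <= motif_len:
        raise ConfigError("window must be longer than the motif")
    rng = child_rng(config.seed, stream)

    # smooth multiplicative sequence bias shared across sites
    rough = rng.normal(0.0, 1.0, length)
    kernel = np.ones(9) / 9.0
    smooth = np.convolve(rough, kernel, mode="same")
    bias = np.exp(0.5 * smooth)
    bias /= bias.mean()

    positions = np.arange(-flank, flank + 1)
    half = motif_len // 2
    core = np.abs(positions) <= half
    rate = base_rate * bias * np.where(core, 1.0 - depletion, 1.0)
    site_counts = rng.poisson(rate, size=(n_sites, length))
    return FootprintTrack(positions=positions, site_counts=site_counts, bias=bias, core_mask=core)


# ---------------------------------------------------------------------------
# motif scenes
# ---------------------------------------------------------------------------

def generate_motif_scenes(
    config: SimConfig,
    motif_len: int = 8,
    window: int = 21,
    stream: str = "motifs",
) -> Tuple[Dict[str, np.ndarray], pd.DataFrame, Set[Tuple[str, str]]]:
    """Plant allelic motif scenes: per scene a PWM, a variant-centred window
    whose reference allele completes the motif consensus and whose alternate
    allele destroys the core position.

    The scene PWMs have one near-deterministic core position (where the
    variant falls) and weakly informative flanks, the shape under which a
    single-base change can dominate the min-max-scaled score (delta > 0.7)
    while the full-length match stays rare under the background model.

    Returns (pwms, scenes table, truth set of (variant, TF)).
    """
    rng = child_rng(config.seed, stream)
    pwms: Dict[str, np.ndarray] = {}
    rows = []
    truth: Set[Tuple[str, str]] = set()
    half = window // 2
    for i, (tf, offset, ref_b, alt_b) in enumerate(config.motif_scenes):
        if not 0 <= offset < motif_len:
            raise ConfigError("variant offset outside motif")
        consensus = rng.integers(0, 4, motif_len)
        pwm = np.full((motif_len, 4), (1 - 0.6) / 3)
        pwm[np.arange(motif_len), consensus] = 0.6
        pwm[offset] = (1 - 0.997) / 3
        pwm[offset, consensus[offset]] = 0.997
        pwm /= pwm.sum(axis=1, keepdims=True)
        pwms[tf] = pwm

        ref_base = BASES[consensus[offset]] if ref_b is None else ref_b
        others = [b for b in BASES if b != ref_base]
        alt_base = others[int(rng.integers(3))] if alt_b is None else alt_b

        seq = rng.choice(BASES, window)
        # place the motif so the variant (window centre) lands at `offset`
        m_start = half - offset
        for k in range(motif_len):
            seq[m_start + k] = BASES[consensus[k]]
        seq[half] = ref_base
        variant_id = f"mv{i}"
        rows.append(
            {
                "variant_id": variant_id,
                "window": "".join(seq),
                "ref": ref_base,
                "alt": alt_base,
                "offset_in_window": half,
            }
        )
        truth.add((variant_id, tf))
    return pwms, pd.DataFrame(rows), truth


# ---------------------------------------------------------------------------
# reporter assay (MPRA) tables
# ---------------------------------------------------------------------------

def generate_mpra_table(
    config: SimConfig,
    variant_ids: Sequence[str] = ("v1",),
    n_tags: int = 25,
    n_batches: int = 5,
    effect: Optional[float] = None,
    stream: str = "mpra",
) -> pd.DataFrame:
    """Reporter activity ratios per variant x allele x strand x tag x batch.

    The alternate allele shifts the mean ratio by ``effect``; strand and
    transfection batch contribute nuisance shifts. 25 tags x 5 batches per
    condition mirror a standard reporter design.
    """
    if effect is None:
        effect = config.mpra_effect
    rng = child_rng(config.seed, stream)
    rows = []
    for v in variant_ids:
        strand_eff = {"fwd": 0.0, "rev": rng.normal(0.0, 0.2)}
        batch_eff = rng.normal(0.0, 0.2, n_batches)
        base = rng.uniform(1.0, 2.0)
        for allele, shift in (("ref", 0.0), ("alt", effect)):
            for strand in ("fwd", "rev"):
                for tag in range(n_tags):
                    for b in range(n_batches):
                        ratio = (
                            base
                            + shift
                            + strand_eff[strand]
                            + batch_eff[b]
                            + rng.normal(0.0, 0.3)
                        )
                        rows.append(
                            {
                                "variant": v,
                                "allele": allele,
                                "strand": strand,
                                "tag": f"tag{tag:02d}",
                                "batch": f"batch{b}",
                                "ratio": max(ratio, 0.0),
                            }
                        )
    return pd.DataFrame(rows)
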