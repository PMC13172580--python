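"""Synthetic gray-matter/white-matter mixture data with full ground truth.

Bulk brain samples are modeled as convex mixtures of a gray-matter (GM) and a
white-matter (WM) expression profile on the log2 scale: a sample with WM
fraction ``w`` has per-gene log2 mean ``(1 - w) * mu_gm + w * mu_wm`` plus
batch offsets and planted disease effects, and counts are drawn from a
negative binomial around that mean. Three sample subgroups differ only in the
distribution of ``w`` (primarily-GM, mixed, and WM-heavy dissections), which
is the latent factor every downstream stage tries to recover. Companion
generators produce cell-type-resolved single cells whose oligodendrocyte
share rises with ``w``, cortical-layer-structured spatial spots, and
metabolite/protein-like abundance matrices with block missingness.

All generators are deterministic given their seed, and the returned
:class:`SimTruth` is sufficient to score every downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from .containers import ExpressionMatrix, SampleTable

__all__ = [
    "TissueProfiles", "SimulationConfig", "SimTruth",
    "make_reference_profiles", "simulate_bulk", "simulate_single_cell",
    "simulate_spatial", "simulate_omics", "CELL_TYPES", "LAYERS",
]

CELL_TYPES = ("excitatory", "inhibitory", "astrocyte", "microglia",
              "oligodendrocyte", "OPC")
LAYERS = ("L1", "L2", "L3", "L4", "L5", "L6", "WM")


@dataclass
class TissueProfiles:
    """Reference GM/WM log2 expression profiles and cell-type means."""

    gene_ids: pd.Index
    mu_gm: np.ndarray
    mu_wm: np.ndarray
    gm_markers: np.ndarray   # bool per gene: mu_gm - mu_wm >= marker_delta
    wm_markers: np.ndarray   # bool per gene: mu_wm - mu_gm >= marker_delta
    celltype_means: pd.DataFrame  # genes x CELL_TYPES, log2 scale
    marker_delta: float

    def __post_init__(self) -> None:
        if np.any(self.gm_markers & self.wm_markers):
            raise ValueError("a gene cannot be both a GM and a WM marker")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def gene_annot(self) -> pd.DataFrame:
        """Minimal gene annotation table (all autosomal)."""
        return pd.DataFrame({"chromosome": "1"}, index=self.gene_ids)


@dataclass
class SimulationConfig:
    """Study conditions for the bulk/single-cell simulators.

    Subgroup w-distributions are Beta laws with means 0.17 (subgroup 1,
    primarily GM), 0.83 (subgroup 2, WM-heavy) and 0.5 (subgroup 3, mixed);
    concentration 150 models three distinct dissection practices whose
    within-practice WM-fraction spread (sd ~0.03-0.04) is small relative to
    the between-practice separation, with tails that still overlap at the
    boundaries. Planted disease effects span fold changes of 1.2-2, the
    magnitude range typical of bulk cortex case-control contrasts.
    """

    n_genes: int = 1500
    n_per_subgroup: tuple[int, int, int] = (40, 40, 40)
    w_beta: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (25.5, 124.5), 2: (124.5, 25.5),
                                 3: (75.0, 75.0)})
    n_batches: int = 3
    batch_sd: float = 0.2           # log2 units
    nb_dispersion: float = 0.2      # var = m + disp * m^2
    libsize_range: tuple[float, float] = (0.7, 1.3)
    n_degs: int = 100
    deg_effect_range: tuple[float, float] = (0.3, 1.0)  # |log2 effect|
    frac_subgroup_specific: float = 0.5
    specific_subgroup: int = 2
    marker_delta: float = 2.0
    confound_diagnosis: float = 0.0  # >0 couples P(AD) to w
    seed: int = 0

    def __post_init__(self) -> None:
        means = {sg: a / (a + b) for sg, (a, b) in self.w_beta.items()}
        if not (means[1] < means[3] < means[2]):
            raise ValueError(
                "subgroup w means must be ordered mean(sg1) < mean(sg3) < mean(sg2)")
        if any(n <= 0 for n in self.n_per_subgroup):
            raise ValueError("n_per_subgroup entries must be positive")


@dataclass
class SimTruth:
    """Ground truth recorded by the simulators."""

    w: pd.Series                      # WM fraction per sample, in [0, 1]
    subgroup: pd.Series               # planted subgroup 1|2|3
    diagnosis: pd.Series              # AD | normal
    batch: pd.Series
    planted_degs: pd.DataFrame        # gene_id, log2_effect, subgroup_specific
    celltype_props: pd.DataFrame | None = None  # samples x CELL_TYPES

    def __post_init__(self) -> None:
        wv = self.w.to_numpy(dtype=float)
        if np.any((wv < 0) | (wv > 1)):
            raise ValueError("w outside [0, 1]")
        if self.celltype_props is not None:
            sums = self.celltype_props.sum(axis=1).to_numpy()
            if not np.allclose(sums, 1.0, atol=1e-8):
                raise ValueError("cell-type proportions must sum to 1")


# --------------------------------------------------------------------------- #
# Reference profiles
# --------------------------------------------------------------------------- #

def make_reference_profiles(n_genes: int, marker_delta: float = 2.0,
                            seed: int = 0) -> TissueProfiles:
    """Draw GM/WM reference profiles with >=5% markers on each side.

    10% of genes are WM markers (``mu_wm`` exceeds ``mu_gm`` by at least
    ``marker_delta``), 10% are GM markers (the reverse), the rest differ by
    less than the marker threshold. Cell-type mean profiles are anchored so
    that oligodendrocytes track the WM profile and neurons the GM profile.
    """
    if n_genes < 50:
        raise ValueError("too few genes (need >= 50)")
    if marker_delta <= 0:
        raise ValueError("marker_delta must be positive")
    rng = np.random.default_rng(seed)
    gene_ids = pd.Index([f"g{i:05d}" for i in range(n_genes)], name="gene_id")
    mu_gm = rng.uniform(2.0, 8.0, n_genes)

    n_marker = max(int(round(0.10 * n_genes)), int(np.ceil(0.05 * n_genes)))
    idx = rng.permutation(n_genes)
    wm_idx, gm_idx = idx[:n_marker], idx[n_marker:2 * n_marker]
    diff = rng.uniform(-0.45, 0.45, n_genes) * marker_delta
    diff[wm_idx] = marker_delta + rng.exponential(0.5, n_marker)
    diff[gm_idx] = -(marker_delta + rng.exponential(0.5, n_marker))
    mu_wm = mu_gm + diff
    wm_markers = diff >= marker_delta
    gm_markers = diff <= -marker_delta

    noise = lambda: rng.normal(0.0, 0.3, n_genes)
    ct = pd.DataFrame({
        "excitatory": mu_gm + noise(),
        "inhibitory": mu_gm + noise(),
        "astrocyte": 0.7 * mu_gm + 0.3 * mu_wm + noise(),
        "microglia": 0.7 * mu_gm + 0.3 * mu_wm + noise(),
        "oligodendrocyte": mu_wm + noise(),
        "OPC": 0.5 * mu_gm + 0.5 * mu_wm + noise(),
    }, index=gene_ids)
    return TissueProfiles(gene_ids, mu_gm, mu_wm, gm_markers, wm_markers,
                          ct, marker_delta)


# --------------------------------------------------------------------------- #
# Bulk cohort
# --------------------------------------------------------------------------- #

def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Negative binomial via gamma-Poisson; Poisson when dispersion -> 0."""
    if np.any(~np.isfinite(mean)):
        raise ValueError("non-finite NB means")
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def _plant_degs(rng: np.random.Generator, profiles: TissueProfiles,
                config: SimulationConfig) -> pd.DataFrame:
    n = min(config.n_degs, profiles.n_genes)
    genes = rng.choice(profiles.n_genes, size=n, replace=False)
    lo, hi = config.deg_effect_range
    effects = rng.uniform(lo, hi, n) * rng.choice([-1.0, 1.0], n)
    n_spec = int(round(config.frac_subgroup_specific * n))
    specific = np.zeros(n, dtype=bool)
    specific[rng.choice(n, size=n_spec, replace=False)] = True
    return pd.DataFrame({
        "gene_id": profiles.gene_ids[genes],
        "log2_effect": effects,
        "subgroup_specific": specific,
        "applies_in_subgroup": np.where(specific, config.specific_subgroup, 0),
    }).set_index("gene_id")


def simulate_bulk(profiles: TissueProfiles, config: SimulationConfig
                  ) -> tuple[ExpressionMatrix, SampleTable, SimTruth]:
    """Simulate a bulk RNA-seq cohort of GM/WM mixtures.

    ``count[g, j] ~ NB(libsize_j * 2**((1 - w_j) mu_gm + w_j mu_wm + batch +
    effect), dispersion)``. Disease effects apply to AD samples only; a
    subgroup-specific effect additionally requires membership in its subgroup.
    RIN and PMI are drawn independently of ``w``.
    """
    if profiles.n_genes != config.n_genes:
        raise ValueError("profiles and config disagree on n_genes")
    rng = np.random.default_rng(config.seed)
    subgroups = np.repeat([1, 2, 3], config.n_per_subgroup)
    n = subgroups.size
    w = np.empty(n)
    for sg, (a, b) in config.w_beta.items():
        m = subgroups == sg
        w[m] = rng.beta(a, b, m.sum())

    p_ad = np.clip(0.5 + config.confound_diagnosis * (w - 0.5), 0.05, 0.95)
    diagnosis = np.where(rng.random(n) < p_ad, "AD", "normal")
    batch = rng.integers(0, config.n_batches, n)
    batch_offsets = rng.normal(0.0, config.batch_sd,
                               (profiles.n_genes, config.n_batches))
    libsize = rng.uniform(*config.libsize_range, n)
    degs = _plant_degs(rng, profiles, config)

    log2_mean = (np.outer(profiles.mu_gm, 1.0 - w)
                 + np.outer(profiles.mu_wm, w)
                 + batch_offsets[:, batch])
    gene_pos = pd.Series(np.arange(profiles.n_genes), index=profiles.gene_ids)
    is_ad = diagnosis == "AD"
    for gid, row in degs.iterrows():
        active = is_ad.copy()
        if row["subgroup_specific"]:
            active &= subgroups == int(row["applies_in_subgroup"])
        log2_mean[gene_pos[gid], active] += row["log2_effect"]

    mean = libsize[None, :] * np.exp2(log2_mean)
    counts = _nb_counts(rng, mean, config.nb_dispersion)

    sample_ids = pd.Index([f"s{j:04d}" for j in range(n)], name="sample_id")
    em = ExpressionMatrix(
        pd.DataFrame(counts.astype(float), index=profiles.gene_ids,
                     columns=sample_ids), "counts")
    age_baseline = rng.uniform(70, 90, n)
    meta = pd.DataFrame({
        "diagnosis": diagnosis,
        "batch": [f"b{b}" for b in batch],
        "RIN": np.clip(rng.normal(7.0, 0.8, n), 4.0, 10.0),
        "PMI": rng.uniform(2.0, 24.0, n),
        "sex": rng.choice(["F", "M"], n),
        "education": rng.integers(8, 21, n).astype(float),
        "age_baseline": age_baseline,
        "age_death": age_baseline + rng.uniform(1.0, 10.0, n),
        "cohort": "sim",
        "region": "DLPFC",
    }, index=sample_ids)
    truth = SimTruth(
        w=pd.Series(w, index=sample_ids, name="w"),
        subgroup=pd.Series(subgroups, index=sample_ids, name="subgroup"),
        diagnosis=pd.Series(diagnosis, index=sample_ids, name="diagnosis"),
        batch=pd.Series(batch, index=sample_ids, name="batch"),
        planted_degs=degs)
    return em, SampleTable(meta), truth


# --------------------------------------------------------------------------- #
# Single cell
# --------------------------------------------------------------------------- #

#: Cell-type composition of pure gray matter and pure white matter
#: (excitatory, inhibitory, astrocyte, microglia, oligodendrocyte, OPC).
#: Neurons dominate GM; oligodendrocytes dominate WM where neuronal somata
#: are nearly absent.
GM_COMPOSITION = np.array([0.55, 0.15, 0.12, 0.05, 0.08, 0.05])
WM_COMPOSITION = np.array([0.02, 0.02, 0.12, 0.06, 0.72, 0.06])


def _celltype_proportions(rng: np.random.Generator, w: np.ndarray,
                          dirichlet_conc: float) -> np.ndarray:
    """Target proportions as the convex blend of GM and WM compositions.

    The oligodendrocyte share is linear in w (p0 + p1 * w with p0 the GM
    share and p1 the WM-GM difference), and the neuronal share falls with w.
    Dirichlet noise around the target; draws renormalize, never error.
    """
    n = w.size
    props = np.empty((n, len(CELL_TYPES)))
    for j in range(n):
        target = (1.0 - w[j]) * GM_COMPOSITION + w[j] * WM_COMPOSITION
        drawn = rng.dirichlet(np.maximum(dirichlet_conc * target, 1e-3))
        props[j] = drawn / drawn.sum()
    return props


def simulate_single_cell(profiles: TissueProfiles, config: SimulationConfig,
                         n_cells_per_sample: int = 80,
                         cell_depth: float = 0.02,
                         cell_dispersion: float = 0.5,
                         dirichlet_conc: float = 200.0,
                         ) -> tuple[scipy.sparse.csr_matrix, pd.Series,
                                    pd.Series, SimTruth]:
    """Simulate labeled single cells whose oligodendrocyte share rises with w.

    Returns (sparse genes x cells counts, cell -> sample map, cell-type
    labels, truth). Cell counts are NB around the cell-type mean profile
    scaled by ``cell_depth`` (cells are far shallower than bulk libraries).
    """
    if min(config.n_per_subgroup) < 3:
        raise ValueError("need >= 3 samples per subgroup")
    if n_cells_per_sample <= 0:
        raise ValueError("sample has no cells")
    rng = np.random.default_rng(config.seed + 1)
    subgroups = np.repeat([1, 2, 3], config.n_per_subgroup)
    n = subgroups.size
    w = np.empty(n)
    for sg, (a, b) in config.w_beta.items():
        m = subgroups == sg
        w[m] = rng.beta(a, b, m.sum())
    sample_ids = pd.Index([f"sc{j:04d}" for j in range(n)], name="sample_id")
    props = _celltype_proportions(rng, w, dirichlet_conc)

    ct_mean_counts = cell_depth * np.exp2(profiles.celltype_means.to_numpy())
    blocks, cell_samples, cell_types = [], [], []
    for j in range(n):
        n_by_type = rng.multinomial(n_cells_per_sample, props[j])
        for t, n_t in enumerate(n_by_type):
            if n_t == 0:
                continue
            mean = np.tile(ct_mean_counts[:, t][:, None], (1, n_t))
            counts = _nb_counts(rng, mean, cell_dispersion)
            blocks.append(scipy.sparse.csr_matrix(counts))
            cell_samples.extend([sample_ids[j]] * n_t)
            cell_types.extend([CELL_TYPES[t]] * n_t)
    counts = scipy.sparse.hstack(blocks, format="csr")
    cell_ids = pd.Index([f"c{i:06d}" for i in range(counts.shape[1])],
                        name="cell_id")
    diagnosis = rng.choice(["AD", "normal"], n)
    truth = SimTruth(
        w=pd.Series(w, index=sample_ids, name="w"),
        subgroup=pd.Series(subgroups, index=sample_ids, name="subgroup"),
        diagnosis=pd.Series(diagnosis, index=sample_ids, name="diagnosis"),
        batch=pd.Series(0, index=sample_ids, name="batch"),
        planted_degs=pd.DataFrame(
            columns=["log2_effect", "subgroup_specific",
                     "applies_in_subgroup"]),
        celltype_props=pd.DataFrame(props, index=sample_ids,
                                    columns=list(CELL_TYPES)))
    return (counts, pd.Series(cell_samples, index=cell_ids, name="sample_id"),
            pd.Series(cell_types, index=cell_ids, name="cell_type"), truth)


# --------------------------------------------------------------------------- #
# Spatial spots
# --------------------------------------------------------------------------- #

def simulate_spatial(profiles: TissueProfiles, n_spots_per_layer: int = 30,
                     seed: int = 0, spot_depth: float = 0.05,
                     spot_dispersion: float = 0.3
                     ) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Simulate cortical-layer-structured spatial spots.

    WM spots draw from the WM profile, L2-L6 from the GM profile, and L1 from
    a 50/50 blend (the molecular layer is sparse and sits against the pia, so
    it resembles neither pure profile). Returns (counts, spot table with
    layer, x, y).
    """
    if n_spots_per_layer < 10:
        raise ValueError("need n_spots_per_layer >= 10")
    rng = np.random.default_rng(seed)
    layer_mu = {
        "L1": 0.5 * profiles.mu_gm + 0.5 * profiles.mu_wm,
        "WM": profiles.mu_wm,
    }
    for lay in ("L2", "L3", "L4", "L5", "L6"):
        layer_mu[lay] = profiles.mu_gm

    cols, layers, xs, ys = [], [], [], []
    for li, lay in enumerate(LAYERS):
        mu = layer_mu[lay]
        lib = spot_depth * rng.uniform(0.8, 1.2, n_spots_per_layer)
        mean = np.outer(np.exp2(mu), lib)
        cols.append(_nb_counts(rng, mean, spot_dispersion))
        layers.extend([lay] * n_spots_per_layer)
        xs.extend(rng.uniform(0, 10, n_spots_per_layer))
        ys.extend(li + rng.uniform(0, 1, n_spots_per_layer))
    counts = np.concatenate(cols, axis=1).astype(float)
    spot_ids = pd.Index([f"spot{i:05d}" for i in range(counts.shape[1])],
                        name="spot_id")
    em = ExpressionMatrix(pd.DataFrame(counts, index=profiles.gene_ids,
                                       columns=spot_ids), "counts")
    spots = pd.DataFrame({"layer": layers, "x": xs, "y": ys}, index=spot_ids)
    return em, spots


# --------------------------------------------------------------------------- #
# Metabolome / proteome analogs
# --------------------------------------------------------------------------- #

def simulate_omics(profiles: TissueProfiles, n_features: int = 120,
                   n_samples: int = 90, missing_rate: float = 0.3,
                   seed: int = 0, effect: float = 2.0, noise_sd: float = 0.6
                   ) -> tuple[ExpressionMatrix, dict[str, pd.DataFrame]]:
    """Simulate an abundance matrix (metabolome/proteome analog) with missingness.

    Features split evenly into WM-like (log abundance rises with w), GM-like
    (falls with w) and neutral. Missingness is missing-at-random per feature
    with per-feature rates drawn uniformly on [0, 2 * missing_rate] (clipped
    at 0.95), so rates span the conventional 70% filtering threshold.
    Returns (matrix with NaN for missing, truth table with per-sample w and
    per-feature class).
    """
    if not (0.0 <= missing_rate < 1.0):
        raise ValueError("missing_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    classes = np.array(["WM-like", "GM-like", "neutral"])[
        np.arange(n_features) % 3]
    base = rng.uniform(4.0, 10.0, n_features)
    sgs = rng.integers(1, 4, n_samples)
    w = np.empty(n_samples)
    for sg, (a, b) in {1: (10.0, 50.0), 2: (50.0, 10.0),
                       3: (30.0, 30.0)}.items():
        m = sgs == sg
        w[m] = rng.beta(a, b, m.sum())
    slope = np.where(classes == "WM-like", effect,
                     np.where(classes == "GM-like", -effect, 0.0))
    values = (base[:, None] + slope[:, None] * w[None, :]
              + rng.normal(0.0, noise_sd, (n_features, n_samples)))
    if missing_rate > 0:
        rates = np.clip(rng.uniform(0.0, 2.0 * missing_rate, n_features),
                        0.0, 0.95)
        miss = rng.random((n_features, n_samples)) < rates[:, None]
        values = np.where(miss, np.nan, values)
    feat_ids = pd.Index([f"f{i:04d}" for i in range(n_features)],
                        name="feature_id")
    samp_ids = pd.Index([f"o{j:04d}" for j in range(n_samples)],
                        name="sample_id")
    em = ExpressionMatrix(pd.DataFrame(values, index=feat_ids,
                                       columns=samp_ids),
                          "abundance", allow_missing=True)
    truth = {
        "features": pd.DataFrame({"feature_class": classes}, index=feat_ids),
        "samples": pd.DataFrame({"w": w, "subgroup": sgs}, index=samp_ids),
    }
    return em, truth
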