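"""Synthetic multi-concentration CITE-Seq generator with known ground truth.

The generator emulates a four-arm antibody titration of human PBMCs:
each arm stains ~2000 droplets at one concentration factor (2x, 1x,
0.2x, 0.04x of the recommended dose), hashtagged per arm, then pooled.
Five major cell types plus an unresolved remainder are drawn at the
study composition.  Per antibody, the mean ADT signal in expressing
cells follows a saturation-binding curve

    signal(c) = S * c / (c + K)

on top of an ambient background that scales linearly with the
concentration factor (free antibody encapsulated in droplets).  Counts
are negative binomial (overdispersed).  Two antibody-level knobs shape
the ground truth:

* the half-saturation constant ``K`` sets the limit of detection (the
  lowest arm at which positive and negative populations separate);
* below an antibody's *optimal* arm, staining is sub-saturating and
  heterogeneous: each expressing cell binds only a Beta-distributed
  fraction u of its full signal (one (alpha, beta) pair per arm-gap
  below the nominal arm), which broadens and dims the stained
  population — degrading separation quality without flipping
  detectability — while keeping every cell bounded by the full signal.

Hashtag counts are modelled as a per-droplet ambient level (not doubled
in doublets) plus a per-cell bound signal, so that same-arm doublets —
whose bound HTO doubles while ambient does not — are separable by the
max/mean ratio rule.  Doublets are same-arm pairs by default (hashing
preceded pooling); HTO-negative droplets carry only a trace ambient
level.  RNA counts give each major type a block of exclusive marker
genes plus mitochondrial genes whose UMI share is drawn from a viability
dependent Beta component.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .model import (
    ConcentrationArm,
    PanelDefinition,
    PanelEntry,
    TitrationDataset,
    ValidationError,
    default_arms,
    validate_arms,
)

TIERS = ("detectable_at_0.04x", "detectable_at_0.2x", "detectable_at_1x",
         "needs_2x", "undetectable", "isotype")

# nominal (optimal) arm per tier, as an index into arms sorted by factor
# ascending: 0 -> 0.04x, 1 -> 0.2x, 2 -> 1x, 3 -> 2x
_NOMINAL_IDX = {"detectable_at_0.04x": 0, "detectable_at_0.2x": 1,
                "detectable_at_1x": 2, "needs_2x": 3}

DEFAULT_COMPOSITION = {
    "B": 0.049, "CD4T": 0.521, "CD8T": 0.121,
    "CM": 0.026, "NK": 0.141, "remaining": 0.142,
}

DEFAULT_TIER_COUNTS = {
    "needs_2x": 7, "detectable_at_1x": 76, "detectable_at_0.2x": 33,
    "detectable_at_0.04x": 8, "undetectable": 64, "isotype": 4,
}


@dataclass(frozen=True)
class AntibodyProfile:
    """Ground-truth parameters for one antibody.

    ``lod_factor`` is the lowest concentration factor at which the
    antibody's populations separate (None for antibodies with no signal);
    ``s_max`` and ``k_half`` parameterize the saturation curve;
    ``expressing_types`` lists the cell types carrying the target.
    """

    antibody_id: str
    target_name: str
    tier: str
    lod_factor: float | None
    s_max: float
    k_half: float
    expressing_types: tuple[str, ...]
    # optional per-antibody heterogeneity schedule: (gap, alpha, beta)
    # for the Beta-distributed bound fraction at arms below nominal
    het_by_gap: tuple[tuple[int, float, float], ...] | None = None

    @property
    def is_isotype(self) -> bool:
        return self.tier == "isotype"


@dataclass
class GeneratorConfig:
    n_cells_per_arm: int = 2000
    composition: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_COMPOSITION))
    arms: list[ConcentrationArm] = field(default_factory=default_arms)
    antibodies: list[AntibodyProfile] = field(default_factory=list)
    signal_max: float = 500.0          # reference saturation mean (counts)
    background_rate: float = 8.0       # ambient ADT mean per antibody at 1x
    nb_dispersion: float = 6.0         # NB size parameter for RNA/ADT
    # sub-saturation heterogeneity: Beta(alpha, beta) bound-fraction
    # parameters by arm-gap below the nominal arm
    het_by_gap: dict[int, tuple[float, float]] = field(
        default_factory=lambda: {1: (1.2, 2.8), 2: (1.0, 3.0), 3: (1.0, 6.0)})
    hto_signal_mean: float = 480.0
    hto_ambient_mean: float = 80.0
    hto_negative_ambient_mean: float = 4.0
    hto_dispersion: float = 400.0      # NB size for HTO counts (low noise)
    hto_negative_fraction: float = 0.02
    doublet_fraction: float = 0.05
    cross_arm_doublets: bool = False
    low_viability_fraction: float = 0.03
    mito_beta_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"viable": (8.0, 192.0), "low": (30.0, 70.0)})
    n_housekeeping_genes: int = 50
    n_mito_genes: int = 10
    markers_per_type: int = 10
    marker_weight: float = 8.0
    rna_total_mean: float = 2000.0

    def __post_init__(self) -> None:
        if abs(sum(self.composition.values()) - 1.0) > 1e-9:
            raise ValidationError("composition must sum to 1")
        if any(not 0 <= f <= 1 for f in self.composition.values()):
            raise ValidationError("composition fractions must be in [0, 1]")
        validate_arms(self.arms)
        for ab in self.antibodies:
            if ab.tier not in TIERS:
                raise ValidationError(f"unknown tier {ab.tier!r}")
            if ab.k_half <= 0:
                raise ValidationError("k_half must be positive")

    # spec-surface views -------------------------------------------------
    @property
    def antibody_tiers(self) -> dict[str, str]:
        return {ab.antibody_id: ab.tier for ab in self.antibodies}

    @property
    def expression_map(self) -> dict[str, tuple[str, ...]]:
        return {ab.antibody_id: ab.expressing_types for ab in self.antibodies}

    def tier_counts(self) -> dict[str, int]:
        counts = {t: 0 for t in TIERS}
        for ab in self.antibodies:
            counts[ab.tier] += 1
        return counts

    def panel(self) -> PanelDefinition:
        return PanelDefinition([
            PanelEntry(ab.antibody_id, ab.target_name, ab.is_isotype)
            for ab in self.antibodies])


@dataclass
class SyntheticTruth:
    """Ground truth tables: one row per droplet and one per antibody."""

    droplets: pd.DataFrame    # barcode, true_type, true_arm, is_doublet, ...
    antibodies: pd.DataFrame  # antibody_id, tier, lod, expressing_types,
                              # detectable_<arm> columns


# ---------------------------------------------------------------------------
# Default panel construction
# ---------------------------------------------------------------------------

# Signal subclasses (S multiplier on signal_max, K, het-by-gap): chosen
# so that each antibody separates cleanly at and above its limit of
# detection and not below it, while the Beta bound-fraction heterogeneity
# grades separation quality down at arms below the tier's nominal
# concentration.  These constants realize the printed tier structure
# (per-arm detectable totals 124/124/116/64, optimal classes 8/33/76/7
# with 64 dropped) under the pipeline's mixture-based calls.
_SUBCLASS_PARAMS = {
    "A": (0.3, 0.01, ()),                              # tier 0.04x, lod 0.04x
    "B": (0.3, 0.3, ((1, 1.0, 3.5),)),                 # tier 0.2x,  lod 0.04x
    "C": (0.8, 2.0, ((1, 1.5, 3.5), (2, 2.0, 2.2))),   # tier 1x,    lod 0.04x
    "D": (1.45, 6.5, ((1, 4.5, 2.0), (2, 1.0, 4.0))),   # tier 1x,    lod 0.2x
    "E": (2.4, 18.0, ((1, 2.0, 2.0), (2, 1.0, 5.0), (3, 1.0, 6.0))),
                                                       # needs_2x,   lod 1x
    "F": (1.0, 14.0, ((1, 1.2, 2.8), (2, 1.0, 3.0), (3, 1.0, 6.0))),
                                                       # tier 1x,    lod 1x
    # G: bright gating markers (CD14/CD16/CD56): optimal at 1x, separable
    # down to 0.04x but with strongly broadened sub-saturated staining at
    # low arms, so monocyte/NK gating degrades with dilution
    "G": (0.8, 2.0, ((1, 0.7, 1.0), (2, 0.5, 1.2))),   # tier 1x,    lod 0.04x
}
_SUBCLASS_TIER = {"A": "detectable_at_0.04x", "B": "detectable_at_0.2x",
                  "C": "detectable_at_1x", "D": "detectable_at_1x",
                  "E": "needs_2x", "F": "detectable_at_1x",
                  "G": "detectable_at_1x"}
_SUBCLASS_LOD = {"A": 0.04, "B": 0.04, "C": 0.04, "D": 0.2, "E": 1.0,
                 "F": 1.0, "G": 0.04}

_MAJOR5 = ("B", "CD4T", "CD8T", "CM", "NK")
# types gateable at the lowest arm (their gating markers separate at 0.04x)
_LOW_ARM_TYPES = ("B", "CD4T", "CD8T")


def _multi_combos(pool: tuple[str, ...]) -> list[tuple[str, ...]]:
    combos = []
    for size in (2, 3, 4):
        combos.extend(itertools.combinations(pool, size))
    return combos


def default_config(n_cells_per_arm: int = 2000) -> GeneratorConfig:
    """The study-condition configuration: a 192-plex panel (188 antibodies
    + 4 isotype controls) whose tier counts are {needs_2x: 7,
    detectable_at_1x: 76, detectable_at_0.2x: 33, detectable_at_0.04x: 8,
    undetectable: 64}, four concentration arms, ~2000 cells per arm, and
    the printed five-type PBMC composition."""
    antibodies: list[AntibodyProfile] = []
    signal_max = 500.0

    # Per-type antigen load is kept balanced across the five major types:
    # real PBMC types each carry a similar number of detectable antigens
    # (a few dozen), and balanced loads keep the CLR centering offset —
    # which depends on how many strong antigens a cell expresses — nearly
    # equal across types, so each antibody's negative population is one
    # coherent cloud rather than a per-type comb.
    load = {t: 0.0 for t in _MAJOR5}

    def add(ab_id, target, subclass, expressing):
        scale, k, het = _SUBCLASS_PARAMS[subclass]
        antibodies.append(AntibodyProfile(
            antibody_id=ab_id, target_name=target,
            tier=_SUBCLASS_TIER[subclass], lod_factor=_SUBCLASS_LOD[subclass],
            s_max=scale * signal_max, k_half=k,
            expressing_types=tuple(expressing), het_by_gap=het))
        for t in expressing:
            if t in load:
                load[t] += 1

    size_cycle = itertools.cycle((2, 3, 4))
    major_total = sum(DEFAULT_COMPOSITION[t] for t in _MAJOR5)

    def balanced_multi(restrict_low_arm: bool) -> tuple[str, ...]:
        """Deterministic greedy: pick the currently least-loaded types,
        capping the combination's share of gated cells at ~80% so that
        multi-type antigens stay clearly distinct from pan antigens."""
        size = next(size_cycle)
        ranked = sorted(_MAJOR5, key=lambda t: (load[t], t))
        chosen = ranked[:size]
        if restrict_low_arm and not set(chosen) & set(_LOW_ARM_TYPES):
            low = min((t for t in _LOW_ARM_TYPES),
                      key=lambda t: (load[t], t))
            chosen[-1] = low
        def coverage(types):
            return sum(DEFAULT_COMPOSITION[t] for t in types) / major_total
        while len(chosen) > 2 and coverage(chosen) > 0.80:
            chosen.remove(max(chosen, key=lambda t: DEFAULT_COMPOSITION[t]))
        return tuple(sorted(chosen))

    idx = itertools.count(1)

    def next_id():
        return f"Ab{next(idx):03d}"

    # -- subclass A: 8 antibodies optimal at 0.04x: 4 pan markers bright
    # in every cell (CD45-like, thresholded at the positive lower limit),
    # the bright lineage markers CD3/CD19 (separable at every dilution),
    # and 2 multi-type antigens
    for i in range(4):
        add(next_id(), f"AgPan{i+1}", "A", _MAJOR5 + ("remaining",))
    add("CD3", "CD3", "A", ("CD4T", "CD8T"))
    add("CD19", "CD19", "A", ("B",))
    for i in range(2):
        add(next_id(), f"AgA{i+1}", "A", balanced_multi(True))
    # -- subclass B: 33 optimal at 0.2x: 6 all-five, 27 multi --------------
    for i in range(6):
        add(next_id(), f"AgPanB{i+1}", "B", _MAJOR5)
    for i in range(27):
        add(next_id(), f"AgBm{i+1}", "B", balanced_multi(True))
    # -- subclass C (20) + gating markers G (3): optimal 1x, lod 0.04x -----
    add("CD4", "CD4", "C", ("CD4T", "CM"))
    add("CD8", "CD8", "C", ("CD8T", "NK"))
    add("CD14", "CD14", "G", ("CM",))
    add("CD16", "CD16", "G", ("NK",))
    add("CD56", "CD56", "G", ("NK",))
    for i in range(18):
        add(next_id(), f"AgCm{i+1}", "C", balanced_multi(True))
    # -- subclass D: 52 optimal at 1x, lod 0.2x ----------------------------
    for i in range(16):
        add(next_id(), f"AgCM{i+1}", "D", ("CM",))
    for i in range(3):
        add(next_id(), f"AgNK{i+1}", "D", ("NK",))
    for i in range(20):
        add(next_id(), f"AgDB{i+1}", "D", ("B",))
    for i in range(6):
        # all-five antigens optimal at 1x: sub-saturated staining below 1x
        # is darker than for the rest of the class, so a third of their
        # cells fall back to background at 0.2x even though the bright
        # remainder still separates
        add(next_id(), f"AgPanD{i+1}", "D", _MAJOR5)
        antibodies[-1] = AntibodyProfile(
            **{**vars(antibodies[-1]),
               "het_by_gap": ((1, 0.5, 0.9), (2, 1.0, 4.0))})
    for i in range(7):
        add(next_id(), f"AgDm{i+1}", "D", balanced_multi(False))
    # -- subclass E: 7 needing the double concentration --------------------
    for i in range(7):
        add(next_id(), f"AgE{i+1}", "E", balanced_multi(False))
    # -- subclass F: 1 at 1x detectable only at >= 1x ----------------------
    add(next_id(), "AgF1", "F", balanced_multi(False))
    # -- 64 antibodies with no signal on PBMCs -----------------------------
    for i in range(64):
        antibodies.append(AntibodyProfile(
            antibody_id=next_id(), target_name=f"AgU{i+1}",
            tier="undetectable", lod_factor=None, s_max=0.0, k_half=1.0,
            expressing_types=()))
    # -- 4 isotype controls ------------------------------------------------
    for i in range(4):
        antibodies.append(AntibodyProfile(
            antibody_id=f"ISO{i+1}", target_name=f"Isotype{i+1}",
            tier="isotype", lod_factor=None, s_max=0.0, k_half=1.0,
            expressing_types=()))

    # Balance the unresolved-remainder type's antigen load too: cells
    # outside the five gated types are real leukocytes with their own
    # surface antigens, and an unloaded remainder would sit at a visibly
    # different CLR centering than every gated type.  Sharing categories
    # consider the five major types only, so this does not alter truth.
    import dataclasses
    avg_major = sum(load.values()) / len(load)
    n_remaining = sum(1 for ab in antibodies
                      if "remaining" in ab.expressing_types)
    for i, ab in enumerate(antibodies):
        if n_remaining >= avg_major:
            break
        if (len(ab.expressing_types) >= 2
                and "remaining" not in ab.expressing_types
                and set(ab.expressing_types) != set(_MAJOR5)):
            antibodies[i] = dataclasses.replace(
                ab, expressing_types=ab.expressing_types + ("remaining",))
            n_remaining += 1

    return GeneratorConfig(n_cells_per_arm=n_cells_per_arm,
                           antibodies=antibodies, signal_max=signal_max)


def truth_detectability(config: GeneratorConfig) -> dict[tuple[str, str], bool]:
    """Expand each antibody's limit of detection to a per-arm boolean
    table: detectable at an arm iff the arm's factor is at or above the
    antibody's lod factor."""
    table: dict[tuple[str, str], bool] = {}
    for ab in config.antibodies:
        if ab.tier not in TIERS:
            raise ValidationError(f"unknown tier {ab.tier!r}")
        for arm in config.arms:
            det = (ab.lod_factor is not None
                   and arm.factor >= ab.lod_factor - 1e-12)
            table[(ab.antibody_id, arm.label)] = det
    return table


# ---------------------------------------------------------------------------
# Dataset generation
# ---------------------------------------------------------------------------

def _nb(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative binomial draws with the given mean matrix and NB size r."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size_param / (size_param + mean[pos])
        out[pos] = rng.negative_binomial(size_param, p)
    return out


def _het_for(config: GeneratorConfig, ab: AntibodyProfile,
             arm_idx: int) -> tuple[float, float] | None:
    """Beta(alpha, beta) bound-fraction parameters at this arm, or None
    when staining is saturated (arm at or above the nominal arm)."""
    nominal = _NOMINAL_IDX.get(ab.tier)
    if nominal is None:
        return None
    gap = max(0, nominal - arm_idx)
    if gap == 0:
        return None
    if ab.het_by_gap is not None:
        table = {g: (a, b) for g, a, b in ab.het_by_gap}
    else:
        table = config.het_by_gap
    if not table:
        return None
    return table.get(gap, table[max(table)])


def _cell_signal_means(config: GeneratorConfig, rng: np.random.Generator,
                       types: np.ndarray, arm_idx: int,
                       factor: float) -> np.ndarray:
    """Per-cell bound-antibody signal means, (n_antibodies x n_cells)."""
    n_ab = len(config.antibodies)
    n = len(types)
    means = np.zeros((n_ab, n))
    for i, ab in enumerate(config.antibodies):
        if ab.s_max <= 0 or not ab.expressing_types:
            continue
        expressing = np.isin(types, ab.expressing_types)
        if not expressing.any():
            continue
        s = ab.s_max * factor / (factor + ab.k_half)
        het = _het_for(config, ab, arm_idx)
        if het is not None:
            u = rng.beta(het[0], het[1], int(expressing.sum()))
            means[i, expressing] = s * u
        else:
            means[i, expressing] = s
    return means


def _rna_gene_table(config: GeneratorConfig) -> tuple[list[str], list[str], dict]:
    """Gene registry: housekeeping, mito, and per-type marker blocks."""
    types = list(DEFAULT_COMPOSITION)
    genes: list[str] = []
    names: list[str] = []
    marker_rows: dict[str, list[int]] = {t: [] for t in types}
    for i in range(config.n_housekeeping_genes):
        genes.append(f"HK{i+1:03d}")
        names.append(f"HK{i+1:03d}")
    mito_rows = []
    for i in range(config.n_mito_genes):
        genes.append(f"MTG{i+1:02d}")
        names.append(f"MT-G{i+1:02d}")
        mito_rows.append(len(genes) - 1)
    for t in types:
        for i in range(config.markers_per_type):
            genes.append(f"MK-{t}-{i+1:02d}")
            names.append(f"MK-{t}-{i+1:02d}")
            marker_rows[t].append(len(genes) - 1)
    return genes, names, {"marker_rows": marker_rows, "mito_rows": mito_rows}


def _cell_rna_means(config: GeneratorConfig, rng: np.random.Generator,
                    types: np.ndarray, mito_fracs: np.ndarray,
                    layout: dict, n_genes: int) -> np.ndarray:
    """Per-cell RNA expected counts, (n_genes x n_cells)."""
    n = len(types)
    weights = np.ones((n_genes, n))
    for t, rows in layout["marker_rows"].items():
        mask = types == t
        if mask.any():
            for r in rows:
                weights[r, mask] = config.marker_weight
    weights[layout["mito_rows"], :] = 0.0
    weights /= weights.sum(axis=0, keepdims=True)
    totals = config.rna_total_mean * np.exp(
        0.25 * rng.standard_normal(n) - 0.03125)
    means = weights * totals * (1.0 - mito_fracs)
    mito_share = totals * mito_fracs / len(layout["mito_rows"])
    means[layout["mito_rows"], :] += mito_share
    return means


def generate_dataset(config: GeneratorConfig,
                     seed: int) -> tuple[TitrationDataset, SyntheticTruth]:
    """Generate one titration dataset plus its ground truth.

    Deterministic for fixed (config, seed); the seed is mandatory — there
    is no implicit global RNG.
    """
    if seed is None:
        raise ValidationError("a seed is required")
    if not config.antibodies:
        raise ValidationError("config has no antibodies")
    rng = np.random.default_rng(seed)

    arms_sorted = sorted(config.arms, key=lambda a: a.factor)
    arm_index = {a.label: i for i, a in enumerate(arms_sorted)}
    type_names = np.array(list(config.composition))
    type_probs = np.array(list(config.composition.values()))
    gene_ids, gene_names, layout = _rna_gene_table(config)
    n_genes = len(gene_ids)
    n_ab = len(config.antibodies)
    hashtag_ids = [a.hashtag_id for a in config.arms]
    n_hto = len(hashtag_ids)
    r = config.nb_dispersion
    r_hto = config.hto_dispersion

    adt_cols, rna_cols, hto_cols = [], [], []
    barcodes: list[str] = []
    truth_rows = []
    bc_counter = itertools.count(1)

    for arm in config.arms:
        n_drop = config.n_cells_per_arm
        n_doublet = int(round(config.doublet_fraction * n_drop))
        n_negative = int(round(config.hto_negative_fraction * n_drop))
        n_singlet = n_drop - n_doublet - n_negative
        n_cells = n_singlet + 2 * n_doublet + n_negative

        types = rng.choice(type_names, size=n_cells, p=type_probs)
        a_idx = arm_index[arm.label]
        sig = _cell_signal_means(config, rng, types, a_idx, arm.factor)

        # viability: per-droplet mito fraction, drawn per cell then shared
        n_lowv = int(round(config.low_viability_fraction * n_drop))
        av, bv = config.mito_beta_params["viable"]
        al, bl = config.mito_beta_params["low"]
        mito = rng.beta(av, bv, size=n_cells)
        lowv_cells = rng.choice(n_cells, size=n_lowv, replace=False) \
            if n_lowv else np.array([], dtype=int)
        mito[lowv_cells] = rng.beta(al, bl, size=n_lowv)
        rna_mean = _cell_rna_means(config, rng, types, mito, layout, n_genes)

        # droplet assembly: first cells are singlets, then doublet pairs,
        # then hto-negative cells
        sing = np.arange(n_singlet)
        pair_a = n_singlet + np.arange(n_doublet)
        pair_b = n_singlet + n_doublet + np.arange(n_doublet)
        neg = n_singlet + 2 * n_doublet + np.arange(n_negative)

        bg = config.background_rate * arm.factor
        adt_mean = np.empty((n_ab, n_drop))
        adt_mean[:, :n_singlet] = bg + sig[:, sing]
        adt_mean[:, n_singlet:n_singlet + n_doublet] = (
            bg + sig[:, pair_a] + sig[:, pair_b])
        adt_mean[:, n_singlet + n_doublet:] = bg + sig[:, neg]
        adt = _nb(rng, adt_mean, r)

        rna_drop = np.empty((n_genes, n_drop))
        rna_drop[:, :n_singlet] = rna_mean[:, sing]
        rna_drop[:, n_singlet:n_singlet + n_doublet] = (
            rna_mean[:, pair_a] + rna_mean[:, pair_b])
        rna_drop[:, n_singlet + n_doublet:] = rna_mean[:, neg]
        rna = rng.poisson(rna_drop)

        # HTO: ambient per droplet + bound signal per contained cell
        hto_mean = np.full((n_hto, n_drop), config.hto_ambient_mean)
        own = hashtag_ids.index(arm.hashtag_id)
        hto_mean[own, :n_singlet] += config.hto_signal_mean
        if config.cross_arm_doublets and n_hto > 1 and n_doublet:
            # stress mode: the second cell of each pair was hashed in a
            # different tube, so its bound HTO lands on another hashtag
            others = [h for h in range(n_hto) if h != own]
            second = rng.choice(others, size=n_doublet)
            dbl_cols = n_singlet + np.arange(n_doublet)
            hto_mean[own, dbl_cols] += config.hto_signal_mean
            hto_mean[second, dbl_cols] += config.hto_signal_mean
        else:
            hto_mean[own, n_singlet:n_singlet + n_doublet] += \
                2 * config.hto_signal_mean
        hto_mean[:, n_singlet + n_doublet:] = config.hto_negative_ambient_mean
        hto = _nb(rng, hto_mean, r_hto)

        adt_cols.append(adt)
        rna_cols.append(rna)
        hto_cols.append(hto)

        lowv_set = set(lowv_cells.tolist())
        for j in range(n_drop):
            barcodes.append(f"BC{next(bc_counter):06d}")
            if j < n_singlet:
                cell_ids, is_dbl, is_neg = [j], False, False
            elif j < n_singlet + n_doublet:
                k = j - n_singlet
                cell_ids, is_dbl, is_neg = [pair_a[k], pair_b[k]], True, False
            else:
                cell_ids = [neg[j - n_singlet - n_doublet]]
                is_dbl, is_neg = False, True
            truth_rows.append({
                "barcode": barcodes[-1],
                "true_type": "+".join(sorted(types[c] for c in cell_ids)),
                "true_arm": arm.label,
                "is_doublet": is_dbl,
                "is_hto_negative": is_neg,
                "is_low_viability": any(c in lowv_set for c in cell_ids),
            })

    dataset = TitrationDataset(
        rna_counts=sp.csr_matrix(np.hstack(rna_cols)),
        adt_counts=sp.csr_matrix(np.hstack(adt_cols)),
        hto_counts=sp.csr_matrix(np.hstack(hto_cols)),
        gene_ids=gene_ids,
        mito_gene_ids=[g for g, nm in zip(gene_ids, gene_names)
                       if nm.startswith("MT-")],
        barcodes=barcodes,
        panel=config.panel(),
        arms=list(config.arms),
        gene_names=gene_names,
    )

    det = truth_detectability(config)
    ab_rows = []
    for ab in config.antibodies:
        row = {"antibody_id": ab.antibody_id, "tier": ab.tier,
               "lod_factor": ab.lod_factor,
               "expressing_types": ";".join(ab.expressing_types)}
        for arm in config.arms:
            row[f"detectable_{arm.label}"] = det[(ab.antibody_id, arm.label)]
        ab_rows.append(row)
    truth = SyntheticTruth(droplets=pd.DataFrame(truth_rows),
                           antibodies=pd.DataFrame(ab_rows))
    return dataset, truth


def clean_config(config: GeneratorConfig) -> GeneratorConfig:
    """A copy with no doublets, no HTO negatives and no low-viability
    cells — the clean-data limit in which QC should remove ~nothing."""
    return replace(config, doublet_fraction=0.0, hto_negative_fraction=0.0,
                   low_viability_fraction=0.0)


def config_from_yaml(path: str) -> GeneratorConfig:
    """Build a generator configuration from a YAML file of overrides.

    The file may set any scalar field of :class:`GeneratorConfig`
    (e.g. ``n_cells_per_arm``, ``doublet_fraction``, ``background_rate``)
    and optionally ``composition``; the antibody panel always comes from
    :func:`default_config`.
    """
    import yaml

    with open(path) as fh:
        overrides = yaml.safe_load(fh) or {}
    if not isinstance(overrides, dict):
        raise ValidationError("run configuration must be a YAML mapping")
    cfg = default_config(
        n_cells_per_arm=int(overrides.pop("n_cells_per_arm", 2000)))
    scalar_fields = {
        "signal_max", "background_rate", "nb_dispersion", "hto_signal_mean",
        "hto_ambient_mean", "hto_negative_ambient_mean", "hto_dispersion",
        "hto_negative_fraction", "doublet_fraction", "cross_arm_doublets",
        "low_viability_fraction", "n_housekeeping_genes", "n_mito_genes",
        "markers_per_type", "marker_weight", "rna_total_mean",
    }
    kwargs = {}
    for key, value in overrides.items():
        if key == "composition":
            kwargs["composition"] = {str(k): float(v) for k, v in value.items()}
        elif key in scalar_fields:
            kwargs[key] = value
        else:
            raise ValidationError(f"unknown configuration key {key!r}")
    if kwargs:
        cfg = replace(cfg, **kwargs)
    return cfg
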