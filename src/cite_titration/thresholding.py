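"""Per-antibody, per-concentration thresholds and detectability calls.

For each antibody at each concentration arm, the CLR values of all
gated major-type cells are fit with a two-component Gaussian mixture.
Separation between the components is measured by Ashman's D,

    D = |mu1 - mu2| / sqrt((sigma1^2 + sigma2^2) / 2),

with D >= 2 the classical cut for clear bimodality.  An antibody is

* detectable with a ``negative95`` threshold (95th percentile of the
  negative component) when the components separate (D >= s_min), the
  upper component holds at least ``min_positive_fraction`` of cells,
  and its mean clears the pooled isotype-control background by a
  margin — the isotype guard keeps discrete low-count background from
  masquerading as a positive population;
* detectable with a ``positive5`` threshold (5th percentile of all
  values) when no negative population exists but nearly all cells sit
  above the isotype background (ubiquitous antigens);
* otherwise not detectable at that arm.

Manually reviewed thresholds can override individual calls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .model import ValidationError


@dataclass(frozen=True)
class ThresholdParams:
    s_min: float = 2.0                  # Ashman's D cut for "clearly separated"
    min_positive_fraction: float = 0.005
    ubiquitous_min_fraction: float = 0.9
    isotype_margin: float = 0.5         # CLR units above isotype background
    min_cells: int = 50
    n_restarts: int = 10
    seed: int = 0


@dataclass
class MixtureFit:
    means: tuple[float, float]          # ordered ascending
    variances: tuple[float, float]
    weights: tuple[float, float]
    assignments: np.ndarray             # 0 = lower component, 1 = upper
    values: np.ndarray
    separation: float                   # Ashman's D
    positive_fraction: float            # weight of the upper component


@dataclass(frozen=True)
class DetectCall:
    antibody_id: str
    arm_label: str
    detectable: bool
    mode: str                           # negative95 | positive5 | manual | none
    threshold: float | None
    separation: float
    # share of assessed cells above the isotype background; ~1 marks a
    # ubiquitously expressed antigen
    above_background_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.detectable != (self.threshold is not None):
            raise ValidationError("threshold must be set iff detectable")
        if (self.mode == "none") != (not self.detectable):
            raise ValidationError("mode 'none' iff not detectable")


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile at position q/100 * (n-1) on the
    sorted values (the frozen convention used throughout)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("percentile of empty values")
    if not 0 <= q <= 100:
        raise ValidationError("q must be in [0, 100]")
    return float(np.percentile(values, q, method="linear"))


def ashman_d(mu1: float, mu2: float, var1: float, var2: float) -> float:
    denom = np.sqrt((var1 + var2) / 2.0)
    if denom == 0:
        return 0.0
    return float(abs(mu1 - mu2) / denom)


def fit_population_model(clr_values, seed: int = 0, min_cells: int = 50,
                         n_restarts: int = 10) -> MixtureFit:
    """Two-component Gaussian mixture on CLR values, best of
    ``n_restarts`` EM starts at a fixed seed; components ordered by mean.

    The components share a single (tied) variance and a small variance
    floor is applied.  Both choices are deliberate: with free variances
    the maximum-likelihood fit of a skewed ADT distribution is a narrow
    bulk plus a wide slab that swallows any minority positive population,
    and on near-discrete low-count data an unfloored component collapses
    onto a single repeated value.  Neither fit resembles the positive/
    negative split a ridge-plot reviewer would draw.
    """
    values = np.asarray(clr_values, dtype=float).ravel()
    if values.size < min_cells:
        raise ValidationError(
            f"insufficient cells for mixture fit: {values.size} < {min_cells}")
    if np.allclose(values, values[0]):
        assignments = np.zeros(values.size, dtype=int)
        return MixtureFit(means=(float(values[0]), float(values[0])),
                          variances=(0.0, 0.0), weights=(1.0, 0.0),
                          assignments=assignments, values=values,
                          separation=0.0, positive_fraction=0.0)
    X = values.reshape(-1, 1)
    # multi-start EM keeping the best likelihood: k-means starts plus
    # deterministic upper-tail splits, so minority positive populations
    # (a rare cell type can be ~2% of cells) are reachable initializations
    tail_fractions = (0.5, 0.25, 0.1, 0.03, 0.01)
    n_kmeans = max(1, n_restarts - len(tail_fractions))
    gm = GaussianMixture(n_components=2, n_init=n_kmeans,
                         random_state=seed, reg_covar=0.02,
                         covariance_type="tied")
    gm.fit(X)
    best = gm
    order_idx = np.argsort(values)
    for f in tail_fractions:
        cut = int(np.floor((1 - f) * values.size))
        lo, hi = values[order_idx[:cut]], values[order_idx[cut:]]
        if lo.size < 2 or hi.size < 2:
            continue
        tied_var = (lo.size * lo.var() + hi.size * hi.var()) / values.size
        init = GaussianMixture(
            n_components=2, n_init=1, random_state=seed, reg_covar=0.02,
            covariance_type="tied",
            weights_init=np.array([lo.size, hi.size]) / values.size,
            means_init=np.array([[lo.mean()], [hi.mean()]]),
            precisions_init=np.array([[1.0 / max(tied_var, 0.02)]]))
        init.fit(X)
        if init.lower_bound_ > best.lower_bound_:
            best = init
    gm = best
    labels = gm.predict(X)
    means = gm.means_.ravel()
    tied = float(np.ravel(gm.covariances_)[0])
    variances = np.array([tied, tied])
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, variances, weights = means[order], variances[order], weights[order]
    remap = np.empty(2, dtype=int)
    remap[order] = np.arange(2)
    assignments = remap[labels]
    return MixtureFit(
        means=(float(means[0]), float(means[1])),
        variances=(float(variances[0]), float(variances[1])),
        weights=(float(weights[0]), float(weights[1])),
        assignments=assignments, values=values,
        separation=ashman_d(means[0], means[1], variances[0], variances[1]),
        positive_fraction=float(weights[1]))


def call_detectability(fit: MixtureFit, isotype_background: float,
                       antibody_id: str, arm_label: str,
                       params: ThresholdParams | None = None) -> DetectCall:
    """Apply the detectability decision rule to one mixture fit.

    ``isotype_background`` is the 95th percentile of the pooled
    isotype-control CLR values for the same arm.
    """
    params = params or ThresholdParams()
    above = float(np.mean(fit.values > isotype_background))
    separated = (fit.separation >= params.s_min
                 and fit.positive_fraction >= params.min_positive_fraction
                 and fit.means[1] >= isotype_background + params.isotype_margin)
    if separated:
        negative_values = fit.values[fit.assignments == 0]
        if negative_values.size == 0:
            negative_values = fit.values
        return DetectCall(antibody_id, arm_label, True, "negative95",
                          percentile(negative_values, 95), fit.separation,
                          above)
    if fit.separation < params.s_min and above >= params.ubiquitous_min_fraction:
        return DetectCall(antibody_id, arm_label, True, "positive5",
                          percentile(fit.values, 5), fit.separation, above)
    return DetectCall(antibody_id, arm_label, False, "none", None,
                      fit.separation, above)


def isotype_background_clr(clr_adt: np.ndarray, isotype_rows: list[int],
                           cell_columns: np.ndarray) -> float:
    """95th percentile of the pooled isotype-control CLR values over the
    given cells — the nonspecific-binding yardstick for one arm."""
    if not isotype_rows:
        raise ValidationError("panel has no isotype controls")
    pooled = clr_adt[np.ix_(isotype_rows, cell_columns)].ravel()
    return percentile(pooled, 95)


def call_all_arms(clr_adt: np.ndarray, annotations, panel,
                  params: ThresholdParams | None = None,
                  gated_only: bool = True) -> list[DetectCall]:
    """Run detectability calling for every (antibody, arm) pair.

    The assessment pool for an arm is its QC-passing cells, restricted to
    gated major-type cells (label != 'remaining') when annotations carry
    gate labels; isotype controls are assessed as background, never
    called detectable.
    """
    params = params or ThresholdParams()
    ann = annotations if isinstance(annotations, pd.DataFrame) else \
        pd.DataFrame([vars(a) for a in annotations])
    iso_ids = set(panel.isotype_ids)
    row_of = {e.antibody_id: i for i, e in enumerate(panel.entries)}
    iso_rows = [row_of[i] for i in panel.isotype_ids]

    calls: list[DetectCall] = []
    arm_labels = [lab for lab in ann["arm_label"].dropna().unique()]
    for arm_label in arm_labels:
        mask = (ann["qc_pass"] & (ann["arm_label"] == arm_label))
        if gated_only and ann["major_type"].notna().any():
            mask &= ann["major_type"].isin(["B", "CD4T", "CD8T", "CM", "NK"])
        cols = np.flatnonzero(mask.to_numpy())
        iso_bg = isotype_background_clr(clr_adt, iso_rows, cols)
        for e in panel.entries:
            if e.antibody_id in iso_ids:
                calls.append(DetectCall(e.antibody_id, arm_label, False,
                                        "none", None, 0.0))
                continue
            values = clr_adt[row_of[e.antibody_id], cols]
            fit = fit_population_model(values, seed=params.seed,
                                       min_cells=params.min_cells,
                                       n_restarts=params.n_restarts)
            calls.append(call_detectability(fit, iso_bg, e.antibody_id,
                                            arm_label, params))
    return calls


def apply_manual_overrides(calls: list[DetectCall],
                           override_table: pd.DataFrame) -> list[DetectCall]:
    """Replace listed (antibody, arm) thresholds/verdicts with manually
    reviewed values; overridden calls carry mode 'manual'."""
    if override_table is None or len(override_table) == 0:
        return list(calls)
    by_key = {(c.antibody_id, c.arm_label): i for i, c in enumerate(calls)}
    out = list(calls)
    for row in override_table.itertuples():
        key = (str(row.antibody_id), str(row.arm_label))
        if key not in by_key:
            raise ValidationError(
                f"override references unknown antibody/arm pair {key}")
        detectable = bool(row.detectable)
        threshold = float(row.threshold) if detectable else None
        old = out[by_key[key]]
        out[by_key[key]] = DetectCall(
            key[0], key[1], detectable,
            "manual" if detectable else "none", threshold, old.separation)
    return out


def calls_to_frame(calls: list[DetectCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {"antibody_id": [c.antibody_id for c in calls],
         "arm_label": [c.arm_label for c in calls],
         "detectable": [c.detectable for c in calls],
         "mode": [c.mode for c in calls],
         "threshold": [c.threshold for c in calls],
         "separation": [c.separation for c in calls],
         "above_background_fraction": [c.above_background_fraction
                                       for c in calls]})


def calls_from_frame(table: pd.DataFrame) -> list[DetectCall]:
    """Inverse of :func:`calls_to_frame` (e.g. after a CSV round trip)."""
    out = []
    for r in table.itertuples():
        detectable = bool(r.detectable)
        out.append(DetectCall(
            str(r.antibody_id), str(r.arm_label), detectable, str(r.mode),
            float(r.threshold) if detectable else None,
            float(r.separation),
            float(getattr(r, "above_background_fraction", 0.0))))
    return out


def binarize(clr_adt: np.ndarray, calls: list[DetectCall], annotations,
             panel) -> np.ndarray:
    """Boolean positivity matrix (antibodies x cells): a cell is positive
    for an antibody iff the antibody is detectable at the cell's arm and
    the cell's CLR strictly exceeds the threshold.  Cells without an arm
    label (non-singlets) are all-negative."""
    ann = annotations if isinstance(annotations, pd.DataFrame) else \
        pd.DataFrame([vars(a) for a in annotations])
    row_of = {e.antibody_id: i for i, e in enumerate(panel.entries)}
    call_of = {(c.antibody_id, c.arm_label): c for c in calls}
    arm_labels = [lab for lab in ann["arm_label"].dropna().unique()]
    for arm_label in arm_labels:
        for e in panel.entries:
            if (e.antibody_id, arm_label) not in call_of:
                raise ValidationError(
                    f"missing call for ({e.antibody_id}, {arm_label})")
    out = np.zeros(clr_adt.shape, dtype=bool)
    arms = ann["arm_label"].to_numpy()
    for arm_label in arm_labels:
        cols = np.flatnonzero(arms == arm_label)
        for e in panel.entries:
            c = call_of[(e.antibody_id, arm_label)]
            if c.detectable:
                row = row_of[e.antibody_id]
                out[row, cols] = clr_adt[row, cols] > c.threshold
    return out
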