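"""Droplet quality control, hashtag demultiplexing, and normalization.

Four independent filters are applied to every droplet:

* viability — mitochondrial UMI fraction must be <= 10% (strict ">"
  removes);
* staining quality — total ADT per droplet must lie in [200, 100000]
  (strict "<"/">" removes, boundaries kept);
* hashtag doublet — max HTO count / mean HTO count > 3 flags a doublet
  (optionally augmented by an externally supplied doublet flag vector);
* negative HTO — max HTO count <= 20 means no hashtag was captured.

A droplet passes QC iff it passes all filters and is an HTO singlet.
Report attribution follows the listing order above: a droplet failing
several filters is counted once, under the first failing reason.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .model import (
    CellAnnotation,
    QCReport,
    TitrationDataset,
    ValidationError,
)


@dataclass(frozen=True)
class QCParams:
    mito_max_fraction: float = 0.10
    adt_min_per_cell: int = 200
    adt_max_per_cell: int = 100_000
    hto_doublet_ratio: float = 3.0
    hto_negative_max: int = 20

    def __post_init__(self) -> None:
        if not 0 < self.mito_max_fraction < 1:
            raise ValidationError("mito_max_fraction must be in (0, 1)")
        if self.adt_min_per_cell >= self.adt_max_per_cell:
            raise ValidationError("adt_min_per_cell must be < adt_max_per_cell")
        if self.hto_doublet_ratio <= 1:
            raise ValidationError("hto_doublet_ratio must be > 1")


@dataclass(frozen=True)
class HTOCall:
    """Demultiplexing verdict for one droplet; verdicts are mutually
    exclusive and exhaustive."""

    verdict: str  # negative | singlet | doublet
    hashtag_id: str | None
    ratio: float


def viability_mask(
    rna_counts: sp.spmatrix,
    gene_ids: list[str],
    mito_gene_ids: list[str],
    params: QCParams,
) -> np.ndarray:
    """True where the droplet is kept (mito fraction <= threshold).

    Droplets with zero total RNA are removed under the viability reason.
    """
    if not mito_gene_ids:
        raise ValidationError("mito gene set is empty; cannot assess viability")
    idx = {g: i for i, g in enumerate(gene_ids)}
    try:
        mito_rows = [idx[g] for g in mito_gene_ids]
    except KeyError as exc:
        raise ValidationError(f"mito gene not in registry: {exc}") from exc
    total = np.asarray(rna_counts.sum(axis=0)).ravel().astype(float)
    mito = np.asarray(rna_counts[mito_rows].sum(axis=0)).ravel().astype(float)
    keep = np.zeros(total.shape, dtype=bool)
    nz = total > 0
    keep[nz] = mito[nz] / total[nz] <= params.mito_max_fraction
    return keep


def staining_quality_mask(adt_counts: sp.spmatrix, params: QCParams) -> np.ndarray:
    """True where total ADT per droplet lies within [adt_min, adt_max]."""
    total = np.asarray(adt_counts.sum(axis=0)).ravel()
    return (total >= params.adt_min_per_cell) & (total <= params.adt_max_per_cell)


def classify_hto(hto_vector: np.ndarray, params: QCParams) -> HTOCall:
    """Classify one droplet's hashtag counts as negative/singlet/doublet.

    Rule order: all hashtags at or below the negative ceiling -> negative;
    max/mean over the vector strictly above the doublet ratio -> doublet;
    otherwise a singlet of the argmax hashtag (ties broken by lowest
    index, deterministically).
    """
    v = np.asarray(hto_vector, dtype=float)
    if v.ndim != 1 or v.size < 2:
        raise ValidationError("HTO vector must be 1-D with >= 2 hashtags")
    vmax = float(v.max())
    mean = float(v.mean())
    ratio = vmax / mean if mean > 0 else 0.0
    if vmax <= params.hto_negative_max:
        return HTOCall("negative", None, ratio)
    if ratio > params.hto_doublet_ratio:
        return HTOCall("doublet", None, ratio)
    return HTOCall("singlet", int(np.argmax(v)), ratio)


def run_qc(
    dataset: TitrationDataset,
    params: QCParams | None = None,
    external_doublet_flags: np.ndarray | None = None,
) -> tuple[list[CellAnnotation], QCReport]:
    """Apply all QC filters and demultiplex hashtags.

    ``external_doublet_flags`` is an optional per-droplet boolean vector
    from an outside doublet caller; flagged droplets fail under the
    doublet reason alongside the HTO-ratio rule.
    """
    params = params or QCParams()
    n = dataset.n_droplets
    if external_doublet_flags is not None:
        external_doublet_flags = np.asarray(external_doublet_flags, dtype=bool)
        if external_doublet_flags.shape != (n,):
            raise ValidationError(
                "external doublet flags are not aligned to droplets")

    viable = viability_mask(dataset.rna_counts, dataset.gene_ids,
                            dataset.mito_gene_ids, params)
    stained = staining_quality_mask(dataset.adt_counts, params)

    hto_dense = np.asarray(dataset.hto_counts.todense(), dtype=float)
    hashtag_ids = [a.hashtag_id for a in dataset.arms]
    arm_of_hashtag = {a.hashtag_id: a.label for a in dataset.arms}

    annotations: list[CellAnnotation] = []
    removed = {"viability": 0, "staining_quality": 0, "doublet": 0,
               "hto_negative": 0}
    for j, bc in enumerate(dataset.barcodes):
        call = classify_hto(hto_dense[:, j], params)
        is_doublet = call.verdict == "doublet" or (
            external_doublet_flags is not None and external_doublet_flags[j])
        arm_label = (arm_of_hashtag[hashtag_ids[call.hashtag_id]]
                     if call.verdict == "singlet" and not is_doublet else None)
        # first-failing-reason attribution, in the fixed filter order
        if not viable[j]:
            reason = "viability"
        elif not stained[j]:
            reason = "staining_quality"
        elif is_doublet:
            reason = "doublet"
        elif call.verdict == "negative":
            reason = "hto_negative"
        else:
            reason = "none"
        qc_pass = reason == "none"
        if not qc_pass:
            removed[reason] += 1
        annotations.append(CellAnnotation(
            barcode=bc, qc_pass=qc_pass, qc_fail_reason=reason,
            arm_label=arm_label))
    report = QCReport(n_input=n, n_removed_per_reason=removed,
                      n_remaining=n - sum(removed.values()))
    return annotations, report


def clr_normalize(adt_counts) -> np.ndarray:
    """Centered log-ratio transform, per droplet (column-wise margin).

    For droplet d with counts x: clr_i = ln(x_i + 1) - mean_j ln(x_j + 1),
    centering across all panel features of that droplet.  This normalizes
    for per-cell differences in ADT capture depth; every output column
    sums to zero.
    """
    x = np.asarray(adt_counts.todense() if sp.issparse(adt_counts)
                   else adt_counts, dtype=float)
    if x.size and np.any(x < 0):
        raise ValidationError("ADT counts must be non-negative")
    logged = np.log1p(x)
    return logged - logged.mean(axis=0, keepdims=True)


def lognorm_rna(rna_counts, scale_total: float = 10_000.0) -> np.ndarray:
    """Depth-normalized log transform: ln(1 + count * scale / droplet_total).

    Zero-total droplets must have been removed upstream (QC contract).
    """
    x = np.asarray(rna_counts.todense() if sp.issparse(rna_counts)
                   else rna_counts, dtype=float)
    totals = x.sum(axis=0, keepdims=True)
    if np.any(totals == 0):
        raise ValidationError(
            "zero-total RNA droplet reached lognorm_rna; QC contract violated")
    return np.log1p(x * scale_total / totals)
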