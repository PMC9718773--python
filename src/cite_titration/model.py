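"""Domain types and count-bundle IO for the titration pipeline.

A titration experiment measures three feature classes per droplet:
gene expression (RNA), antibody capture (ADT) and multiplexing capture
(HTO).  The on-disk layout is the 10x triplet convention: one Matrix
Market sparse matrix over all features, a ``features.tsv`` naming each
row and its feature class, and a ``barcodes.tsv`` naming each column.
All in-memory matrices are oriented features x droplets.
"""

from __future__ import annotations

import gzip
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

GEX_TYPE = "Gene Expression"
ADT_TYPE = "Antibody Capture"
HTO_TYPE = "Multiplexing Capture"
FEATURE_TYPES = (GEX_TYPE, ADT_TYPE, HTO_TYPE)

ARM_LABELS = ("2x", "1x", "0.2x", "0.04x")
ARM_FACTORS = {"2x": 2.0, "1x": 1.0, "0.2x": 0.2, "0.04x": 0.04}

MAJOR_TYPES = ("B", "CD4T", "CD8T", "CM", "NK", "remaining")

QC_FAIL_REASONS = ("viability", "staining_quality", "doublet", "hto_negative", "none")


class ValidationError(ValueError):
    """Raised when inputs violate a structural contract."""


class SchemaError(ValidationError):
    """Raised when a table is missing required columns."""


@dataclass(frozen=True)
class PanelEntry:
    """One antibody in the panel; isotype controls carry no target expectation."""

    antibody_id: str
    target_name: str
    is_isotype_control: bool
    barcode_tag: str = ""


@dataclass
class PanelDefinition:
    entries: list[PanelEntry]

    def __post_init__(self) -> None:
        ids = [e.antibody_id for e in self.entries]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValidationError(f"duplicate antibody_id in panel: {sorted(dupes)}")

    @property
    def n_total(self) -> int:
        return len(self.entries)

    @property
    def antibody_ids(self) -> list[str]:
        return [e.antibody_id for e in self.entries]

    @property
    def isotype_ids(self) -> list[str]:
        return [e.antibody_id for e in self.entries if e.is_isotype_control]

    @property
    def n_isotype(self) -> int:
        return len(self.isotype_ids)


@dataclass(frozen=True)
class ConcentrationArm:
    """One staining condition: a dilution factor relative to the
    manufacturer-recommended concentration, identified by its hashtag."""

    label: str
    factor: float
    hashtag_id: str

    def __post_init__(self) -> None:
        if self.factor <= 0:
            raise ValidationError(f"arm factor must be positive, got {self.factor}")


def default_arms() -> list[ConcentrationArm]:
    return [
        ConcentrationArm(lab, ARM_FACTORS[lab], f"HTO{i+1}")
        for i, lab in enumerate(ARM_LABELS)
    ]


def validate_arms(arms: list[ConcentrationArm]) -> None:
    labels = [a.label for a in arms]
    if len(set(labels)) != len(labels):
        raise ValidationError("arm labels must be unique")
    if sum(1 for a in arms if a.factor == 1.0) != 1:
        raise ValidationError("exactly one arm must have factor 1 (recommended)")


@dataclass
class TitrationDataset:
    """Aligned sparse count matrices for one titration run.

    All three matrices share the droplet axis (same barcodes, same
    order); counts are non-negative integers.
    """

    rna_counts: sp.csr_matrix
    adt_counts: sp.csr_matrix
    hto_counts: sp.csr_matrix
    gene_ids: list[str]
    mito_gene_ids: list[str]
    barcodes: list[str]
    panel: PanelDefinition
    arms: list[ConcentrationArm] = field(default_factory=default_arms)
    gene_names: list[str] | None = None

    def __post_init__(self) -> None:
        if self.gene_names is None:
            self.gene_names = list(self.gene_ids)
        if len(self.gene_names) != len(self.gene_ids):
            raise ValidationError("gene_names does not match gene registry")
        n = len(self.barcodes)
        for name, m in (("rna", self.rna_counts), ("adt", self.adt_counts),
                        ("hto", self.hto_counts)):
            if m.shape[1] != n:
                raise ValidationError(
                    f"{name} matrix has {m.shape[1]} droplets, expected {n}")
        if self.rna_counts.shape[0] != len(self.gene_ids):
            raise ValidationError("rna row count does not match gene registry")
        if self.adt_counts.shape[0] != self.panel.n_total:
            raise ValidationError(
                f"adt row count {self.adt_counts.shape[0]} != panel size "
                f"{self.panel.n_total}")
        if self.hto_counts.shape[0] != len(self.arms):
            raise ValidationError("hto row count does not match number of arms")
        unknown_mito = set(self.mito_gene_ids) - set(self.gene_ids)
        if unknown_mito:
            raise ValidationError(f"mito genes not in registry: {sorted(unknown_mito)}")
        for name, m in (("rna", self.rna_counts), ("adt", self.adt_counts),
                        ("hto", self.hto_counts)):
            data = m.data
            if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
                raise ValidationError(f"{name} counts must be non-negative integers")

    @property
    def n_droplets(self) -> int:
        return len(self.barcodes)

    def arm_by_hashtag(self) -> dict[str, ConcentrationArm]:
        return {a.hashtag_id: a for a in self.arms}

    def arm_by_label(self) -> dict[str, ConcentrationArm]:
        return {a.label: a for a in self.arms}


@dataclass
class CellAnnotation:
    """Per-droplet QC and typing state.

    ``arm_label`` is set iff the droplet is an HTO singlet; ``major_type``
    is set only for QC-passing droplets (after gating).
    """

    barcode: str
    qc_pass: bool
    qc_fail_reason: str = "none"
    arm_label: str | None = None
    major_type: str | None = None

    def __post_init__(self) -> None:
        if self.qc_fail_reason not in QC_FAIL_REASONS:
            raise ValidationError(f"unknown qc_fail_reason {self.qc_fail_reason!r}")


@dataclass
class QCReport:
    n_input: int
    n_removed_per_reason: dict[str, int]
    n_remaining: int

    def __post_init__(self) -> None:
        if self.n_input - sum(self.n_removed_per_reason.values()) != self.n_remaining:
            raise ValidationError("QC report does not balance")

    def to_json(self) -> str:
        return json.dumps(
            {"n_input": self.n_input,
             "n_removed_per_reason": self.n_removed_per_reason,
             "n_remaining": self.n_remaining}, indent=2)


def annotations_to_frame(annotations: list[CellAnnotation]) -> pd.DataFrame:
    return pd.DataFrame(
        {"barcode": [a.barcode for a in annotations],
         "qc_pass": [a.qc_pass for a in annotations],
         "qc_fail_reason": [a.qc_fail_reason for a in annotations],
         "arm_label": [a.arm_label for a in annotations],
         "major_type": [a.major_type for a in annotations]})


# ---------------------------------------------------------------------------
# Count-bundle IO (10x triplet layout)
# ---------------------------------------------------------------------------

def _open_maybe_gz(path: str, mode: str = "rt"):
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def _find(directory: str, stem: str) -> str:
    for cand in (stem, stem + ".gz"):
        p = os.path.join(directory, cand)
        if os.path.exists(p):
            return p
    raise FileNotFoundError(
        f"count bundle is missing {stem}[.gz] in {directory}")


def read_count_bundle(
    directory: str,
    mito_prefix: str = "MT-",
    arms: list[ConcentrationArm] | None = None,
) -> TitrationDataset:
    """Read a 10x-style triplet bundle and split it by feature class.

    ``features.tsv`` must have three columns (id, name, feature_type);
    feature_type assigns every row to exactly one of gene expression,
    antibody capture or multiplexing capture.  Mitochondrial genes are
    selected by gene-name prefix (default ``MT-``).
    """
    mtx_path = _find(directory, "matrix.mtx")
    feat_path = _find(directory, "features.tsv")
    bc_path = _find(directory, "barcodes.tsv")

    with _open_maybe_gz(mtx_path, "rb") as fh:
        mat = sp.csr_matrix(scipy.io.mmread(fh))
    if mat.data.size and np.any(mat.data != np.round(mat.data)):
        raise ValidationError("matrix contains non-integer counts")
    mat = mat.astype(np.int64)

    features = pd.read_csv(feat_path, sep="\t", header=None,
                           names=["id", "name", "feature_type"], dtype=str)
    if features["feature_type"].isna().any():
        raise SchemaError("features table must have 3 columns (id, name, type)")
    with _open_maybe_gz(bc_path) as fh:
        barcodes = [line.strip() for line in fh if line.strip()]

    if mat.shape[0] != len(features):
        raise ValidationError(
            f"matrix has {mat.shape[0]} rows but features table has {len(features)}")
    if mat.shape[1] != len(barcodes):
        raise ValidationError(
            f"matrix has {mat.shape[1]} columns but {len(barcodes)} barcodes")

    unknown = set(features["feature_type"]) - set(FEATURE_TYPES)
    if unknown:
        raise ValidationError(f"unknown feature_type values: {sorted(unknown)}")

    is_gex = (features["feature_type"] == GEX_TYPE).to_numpy()
    is_adt = (features["feature_type"] == ADT_TYPE).to_numpy()
    is_hto = (features["feature_type"] == HTO_TYPE).to_numpy()
    if not is_adt.any():
        raise ValidationError("bundle has no antibody-capture rows (panel empty)")

    gene_ids = features.loc[is_gex, "id"].tolist()
    gene_names = features.loc[is_gex, "name"].tolist()
    mito_gene_ids = [g for g, nm in zip(gene_ids, gene_names)
                     if nm.startswith(mito_prefix)]

    adt_rows = features.loc[is_adt]
    panel = PanelDefinition([
        PanelEntry(antibody_id=r.id, target_name=r.name,
                   is_isotype_control=r.name.lower().startswith("isotype"))
        for r in adt_rows.itertuples()
    ])
    hto_ids = features.loc[is_hto, "id"].tolist()
    if arms is None:
        arms = [ConcentrationArm(ARM_LABELS[i] if i < len(ARM_LABELS) else f"arm{i}",
                                 ARM_FACTORS.get(ARM_LABELS[i], 1.0) if i < len(ARM_LABELS) else 1.0,
                                 h)
                for i, h in enumerate(hto_ids)]

    return TitrationDataset(
        rna_counts=sp.csr_matrix(mat[is_gex]),
        adt_counts=sp.csr_matrix(mat[is_adt]),
        hto_counts=sp.csr_matrix(mat[is_hto]),
        gene_ids=gene_ids,
        mito_gene_ids=mito_gene_ids,
        barcodes=barcodes,
        panel=panel,
        arms=arms,
        gene_names=gene_names,
    )


def write_count_bundle(dataset: TitrationDataset, directory: str) -> None:
    """Write the triplet layout readable by :func:`read_count_bundle`.

    Integer counts are preserved exactly; the feature order is canonical
    (genes, then antibodies, then hashtags) so write -> read -> write is
    byte-identical.
    """
    os.makedirs(directory, exist_ok=True)
    stacked = sp.vstack([dataset.rna_counts, dataset.adt_counts,
                         dataset.hto_counts]).tocoo()
    # canonical ordering of the payload: row-major sorted entries
    order = np.lexsort((stacked.col, stacked.row))
    canonical = sp.coo_matrix(
        (stacked.data[order], (stacked.row[order], stacked.col[order])),
        shape=stacked.shape)
    with open(os.path.join(directory, "matrix.mtx"), "wb") as fh:
        scipy.io.mmwrite(fh, canonical, field="integer")

    rows = []
    for gid, name in zip(dataset.gene_ids, dataset.gene_names):
        rows.append((gid, name, GEX_TYPE))
    for e in dataset.panel.entries:
        rows.append((e.antibody_id, e.target_name, ADT_TYPE))
    for a in dataset.arms:
        rows.append((a.hashtag_id, a.hashtag_id, HTO_TYPE))
    pd.DataFrame(rows).to_csv(os.path.join(directory, "features.tsv"),
                              sep="\t", header=False, index=False)
    with open(os.path.join(directory, "barcodes.tsv"), "w") as fh:
        fh.write("\n".join(dataset.barcodes) + "\n")


def load_panel(table_path: str) -> PanelDefinition:
    """Load a panel definition table (CSV or TSV with a header row).

    Required columns: ``antibody_id``, ``target_name``,
    ``is_isotype_control``.
    """
    sep = "\t" if table_path.endswith((".tsv", ".tsv.gz")) else ","
    table = pd.read_csv(table_path, sep=sep)
    required = {"antibody_id", "target_name", "is_isotype_control"}
    missing = required - set(table.columns)
    if missing:
        raise SchemaError(f"panel table missing columns: {sorted(missing)}")
    if len(table) == 0:
        raise ValidationError("panel table is empty")
    dupes = table["antibody_id"][table["antibody_id"].duplicated()]
    if len(dupes):
        raise ValidationError(
            f"duplicate antibody_id in panel table: {sorted(set(dupes))}")
    entries = [
        PanelEntry(antibody_id=str(r.antibody_id), target_name=str(r.target_name),
                   is_isotype_control=bool(r.is_isotype_control),
                   barcode_tag=str(getattr(r, "barcode_tag", "")))
        for r in table.itertuples()
    ]
    return PanelDefinition(entries)
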