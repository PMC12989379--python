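"""Reading, writing and validating the pipeline's file formats.

Canonical on-disk formats are tab-separated text: feature-by-sample
matrices (first column = feature id, header row = sample ids), a clinical
table (sample_id, recurrence, grade), and GMT gene-set collections
(set name TAB description TAB member symbols...). Comma-separated
matrices are accepted behind ``sep=","``.

Feature ids are namespaced as ``"<layer>:<id>"`` in every cross-layer
structure (connectome, integrated matrix) because the same gene symbol
legitimately occurs in several layers — e.g. a gene that is both
differentially methylated and differentially expressed; ``display_symbol``
recovers the raw symbol for reporting and enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from omicnet import LAYERS
from omicnet.errors import AlignmentError, FormatError

log = logging.getLogger(__name__)

VALID_GRADES = (1, 2, 3)
VALID_RECURRENCE = ("no", "yes")


@dataclass
class OmicsLayer:
    """One feature-by-sample matrix tagged with its omic layer.

    ``values`` is a dense DataFrame with feature ids as the index and
    sample ids as the columns. Methylation values are beta proportions
    in [0, 1]; RNA and protein values are normalized (log2-scale)
    expression.
    """

    layer_name: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.layer_name not in LAYERS:
            raise FormatError(f"unknown layer name {self.layer_name!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique())
            raise FormatError(
                f"duplicate feature ids in {self.layer_name} layer: {dupes}"
            )
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique())
            raise FormatError(
                f"duplicate sample ids in {self.layer_name} layer: {dupes}"
            )
        if self.layer_name == "methylation" and self.values.size:
            arr = self.values.to_numpy(dtype=float)
            finite = np.isfinite(arr)
            bad = finite & ((arr < 0) | (arr > 1))
            if bad.any():
                rows = sorted(self.values.index[bad.any(axis=1)])
                raise FormatError(
                    "methylation beta values outside [0,1] in rows: "
                    f"{rows[:10]}"
                )

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def namespaced(self) -> pd.DataFrame:
        """Matrix re-indexed with layer-namespaced feature ids."""
        out = self.values.copy()
        out.index = [namespace_feature(self.layer_name, f) for f in out.index]
        return out


def namespace_feature(layer: str, feature_id: str) -> str:
    return f"{layer}:{feature_id}"


def display_symbol(namespaced_id: str) -> str:
    """Raw symbol behind a namespaced id ('rna:CHN2' -> 'CHN2')."""
    return namespaced_id.split(":", 1)[1] if ":" in namespaced_id else namespaced_id


def layer_of(namespaced_id: str) -> str:
    return namespaced_id.split(":", 1)[0]


@dataclass
class ClinicalTable:
    """Per-sample recurrence status ('yes'/'no') and WHO grade (1-3)."""

    table: pd.DataFrame  # index sample_id, columns recurrence, grade

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise FormatError("duplicate sample ids in clinical table")
        missing = {"recurrence", "grade"} - set(t.columns)
        if missing:
            raise FormatError(f"clinical table missing columns {sorted(missing)}")
        bad_rec = set(t["recurrence"]) - set(VALID_RECURRENCE)
        if bad_rec:
            raise FormatError(f"invalid recurrence values {sorted(bad_rec)}")
        bad_grade = set(int(g) for g in t["grade"]) - set(VALID_GRADES)
        if bad_grade:
            raise FormatError(f"invalid WHO grades {sorted(bad_grade)}")
        self.table = t.assign(grade=t["grade"].astype(int))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def group_mask(self, contrast: str) -> tuple[np.ndarray, np.ndarray, str, str]:
        """Boolean masks (a, b) for the two groups of a named contrast."""
        t = self.table
        if contrast == "recurrence":
            a = (t["recurrence"] == "no").to_numpy()
            b = (t["recurrence"] == "yes").to_numpy()
            return a, b, "no", "yes"
        if contrast == "g1_vs_g2":
            return (
                (t["grade"] == 1).to_numpy(),
                (t["grade"] == 2).to_numpy(),
                "G1",
                "G2",
            )
        if contrast == "g2_vs_g3":
            return (
                (t["grade"] == 2).to_numpy(),
                (t["grade"] == 3).to_numpy(),
                "G2",
                "G3",
            )
        raise FormatError(f"unknown contrast {contrast!r}")


@dataclass
class GeneSetCollection:
    """Named gene sets: set name -> (description, member symbols)."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> list[str]:
        return self.sets[name][1]


# ---------------------------------------------------------------------------
# readers / writers


def read_layer(path, layer_name: str, sep: str = "\t") -> OmicsLayer:
    """Read a feature-by-sample matrix; drop non-numeric/missing rows.

    Rows containing any missing or non-numeric cell are removed and the
    count is logged; duplicate feature or sample ids and out-of-range
    methylation betas raise :class:`FormatError`.
    """
    df = pd.read_csv(path, sep=sep, index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df = df.apply(pd.to_numeric, errors="coerce")
    incomplete = df.isna().any(axis=1)
    if incomplete.any():
        log.warning(
            "read_layer(%s): dropped %d/%d features with missing or "
            "non-numeric cells",
            layer_name,
            int(incomplete.sum()),
            len(df),
        )
        df = df.loc[~incomplete]
    return OmicsLayer(layer_name=layer_name, values=df.astype(float))


def write_layer(layer: OmicsLayer, path, sep: str = "\t") -> None:
    layer.values.to_csv(path, sep=sep, index_label="feature_id")


def read_clinical(path, sep: str = "\t") -> ClinicalTable:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return ClinicalTable(table=df)


def write_clinical(clinical: ClinicalTable, path, sep: str = "\t") -> None:
    clinical.table.to_csv(path, sep=sep, index_label="sample_id")


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name TAB description TAB members...).

    Duplicate member symbols within a set are deduplicated preserving
    order; a line with fewer than three fields raises FormatError with
    its line number.
    """
    sets: dict[str, tuple[str, list[str]]] = {}
    with open(path) as fh:
        n_lines = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, desc, *members = fields
            if name in sets:
                raise FormatError(f"GMT line {lineno}: duplicate set name {name!r}")
            seen: dict[str, None] = {}
            for m in members:
                if m and m not in seen:
                    seen[m] = None
            if not seen:
                raise FormatError(f"GMT line {lineno}: set {name!r} is empty")
            sets[name] = (desc, list(seen))
    if n_lines == 0:
        log.warning("read_gmt(%s): empty file, returning empty collection", path)
    return GeneSetCollection(sets=sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def align_samples(
    layers: list[OmicsLayer], clinical: ClinicalTable
) -> tuple[list[OmicsLayer], ClinicalTable]:
    """Restrict all layers and the clinical table to their common samples.

    The shared order is the first layer's sample order restricted to the
    intersection, so the call is idempotent. Raises AlignmentError when
    the intersection is empty.
    """
    common = set(layers[0].sample_ids)
    for layer in layers[1:]:
        common &= set(layer.sample_ids)
    common &= set(clinical.sample_ids)
    if not common:
        raise AlignmentError("no samples shared across all layers and clinical table")
    order = [s for s in layers[0].sample_ids if s in common]
    log.info("align_samples: %d shared samples", len(order))
    aligned = [
        OmicsLayer(layer_name=ly.layer_name, values=ly.values.loc[:, order])
        for ly in layers
    ]
    return aligned, ClinicalTable(table=clinical.table.loc[order])
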