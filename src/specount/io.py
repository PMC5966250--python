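"""Tabular input/output with strict validation.

Three table kinds flow through the pipeline:

* a spectral-count matrix (proteins x samples, non-negative integers) with a
  sample -> group/case map — the discovery-stage substrate;
* a protein annotation table (accession -> length in amino acids, symbol) —
  the length term of NSAF;
* a patient cohort table (one row per patient: metastasis group, covariates,
  per-marker IHC positivity, follow-up times and event flags) — the
  validation-stage substrate.

Conventions: TSV for matrices and reports, CSV for the cohort; UTF-8,
decimal point ".", mandatory header row.  Missing count cells are rejected,
never imputed as zero — an absent identification must be an explicit 0
written by the producer, because presence/absence drives the Venn stage.
Accessions are opaque text and are never parsed for meaning.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParseError, ValidationError

GROUPS = ("PT", "LT")

METASTASIS_GROUPS = ("synchronous", "metachronous", "none")
WHO_GRADES = ("G1", "G2", "G3")
ENETS_STAGES = ("I", "II", "III", "IV")

#: columns every cohort CSV must carry, in canonical order; marker columns
#: (``marker_<SYMBOL>``, binary) may appear in any number after these.
COHORT_BASE_COLUMNS = [
    "patient_id",
    "group",
    "gender",
    "age",
    "function_type",
    "who_grade",
    "ki67",
    "mitotic_count",
    "tumor_size_mm",
    "lymph_node_metastasis",
    "vascular_invasion",
    "lymphatic_invasion",
    "enets_stage",
    "liver_rfs_months",
    "liver_recurrence",
    "os_months",
    "death",
]


@dataclass
class SpectralCountMatrix:
    """Proteins x samples integer count matrix with sample metadata.

    ``counts`` is indexed by accession (rows) and sample ID (columns);
    ``groups`` and ``cases`` map each sample to its tissue group
    (``"PT"`` primary pancreatic tumor / ``"LT"`` paired liver metastasis)
    and its case identifier.
    """

    counts: pd.DataFrame
    groups: pd.Series
    cases: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.counts.index.duplicated().any():
            dup = self.counts.index[self.counts.index.duplicated()][0]
            raise ValidationError(f"duplicate accession {dup!r} in count matrix")
        if self.counts.columns.duplicated().any():
            dup = self.counts.columns[self.counts.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample ID {dup!r} in count matrix")
        unmapped = [s for s in self.counts.columns if s not in self.groups.index]
        if unmapped:
            raise ValidationError(
                f"samples missing from the group map: {unmapped}"
            )
        bad_group = self.groups[~self.groups.isin(GROUPS)]
        if len(bad_group):
            raise ValidationError(
                f"sample {bad_group.index[0]!r} has group "
                f"{bad_group.iloc[0]!r}; expected one of {GROUPS}"
            )
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValidationError("counts must be integers")
        if (arr < 0).any():
            i, j = np.argwhere(arr < 0)[0]
            raise ValidationError(
                f"negative count for protein {self.counts.index[i]!r}, "
                f"sample {self.counts.columns[j]!r}"
            )

    @property
    def accessions(self) -> pd.Index:
        return self.counts.index

    def samples(self, group: str | None = None) -> list[str]:
        if group is None:
            return list(self.counts.columns)
        return [s for s in self.counts.columns if self.groups[s] == group]

    def submatrix(self, group: str) -> pd.DataFrame:
        return self.counts[self.samples(group)]

    def relabelled(self) -> "SpectralCountMatrix":
        """Swap PT and LT group labels (used by antisymmetry checks)."""
        swapped = self.groups.map({"PT": "LT", "LT": "PT"})
        return SpectralCountMatrix(self.counts.copy(), swapped, self.cases.copy())


@dataclass
class ProteinAnnotationTable:
    """Accession -> (length in amino acids, symbol, optional description)."""

    table: pd.DataFrame  # index accession; columns: length, symbol, description

    def __post_init__(self) -> None:
        if self.table.index.duplicated().any():
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValidationError(f"duplicate accession {dup!r} in annotation table")
        if (self.table["length"] < 1).any():
            bad = self.table.index[self.table["length"] < 1][0]
            raise ValidationError(f"non-positive length for accession {bad!r}")

    @property
    def lengths(self) -> pd.Series:
        return self.table["length"]

    @property
    def symbols(self) -> pd.Series:
        return self.table["symbol"]


@dataclass
class CohortTable:
    """Per-patient clinical table for the validation stage.

    One row per patient.  ``group`` is the metastasis group (synchronous /
    metachronous / none); marker columns are binary IHC positivity flags
    (positive == at least 10% of tumor cells stained, thresholded upstream).
    Liver recurrence-free survival (RFS) time is absent (NaN) for synchronous
    patients, who are excluded from all survival analyses downstream.
    """

    table: pd.DataFrame
    marker_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        t = self.table
        if len(t) == 0:
            raise ValidationError("cohort table is empty")
        missing = [c for c in COHORT_BASE_COLUMNS if c not in t.columns]
        if missing:
            raise ValidationError(f"cohort table missing columns: {missing}")
        if not self.marker_columns:
            self.marker_columns = [c for c in t.columns if c.startswith("marker_")]
        self._validate_rows()

    def _validate_rows(self) -> None:
        t = self.table

        def bad_row(mask: pd.Series, what: str) -> None:
            if mask.any():
                row = t.index[mask][0]
                pid = t.loc[row, "patient_id"]
                raise ValidationError(f"{what} (patient {pid!r}, row {row})")

        bad_row(~t["group"].isin(METASTASIS_GROUPS), "unknown metastasis group")
        bad_row(~t["who_grade"].isin(WHO_GRADES), "unknown WHO grade")
        bad_row(~t["enets_stage"].isin(ENETS_STAGES), "unknown ENETS stage")
        bad_row((t["ki67"] < 0) | (t["ki67"] > 100), "Ki-67 outside [0, 100]")
        bad_row(t["tumor_size_mm"] <= 0, "non-positive tumor size")
        bad_row(t["mitotic_count"] < 0, "negative mitotic count")
        for col in ("liver_rfs_months", "os_months"):
            bad_row(t[col] < 0, f"negative time in {col}")
        for col in ("liver_recurrence", "death", *self.marker_columns):
            bad_row(~t[col].isin([0, 1]) & t[col].notna(), f"non-binary flag in {col}")
        sync = t["group"] == "synchronous"
        if (sync & t["liver_rfs_months"].notna()).any():
            warnings.warn(
                "synchronous-metastasis patients carry a liver-RFS time; "
                "the field is ignored downstream",
                stacklevel=3,
            )

    def group_sizes(self) -> dict[str, int]:
        vc = self.table["group"].value_counts()
        return {g: int(vc.get(g, 0)) for g in METASTASIS_GROUPS}

    def at_risk(self) -> pd.DataFrame:
        """Patients eligible for liver-RFS analysis (synchronous excluded)."""
        return self.table[self.table["group"] != "synchronous"].copy()


# ---------------------------------------------------------------------------
# readers / writers


def read_count_table(path: str | Path, group_map_path: str | Path) -> SpectralCountMatrix:
    """Read a TSV count matrix plus its sample -> group(/case) map.

    The matrix TSV has accessions in the first column and one column per
    sample; the map TSV has columns ``sample``, ``group`` and optionally
    ``case``.  Non-integer or negative cells and unmapped samples are
    rejected with errors naming the offending protein and sample.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.empty and raw.columns.empty:
        raise ParseError(f"empty count table: {path}")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() | (numeric != numeric.round()) | (numeric < 0)
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ParseError(
            f"count cell {raw.iat[i, j]!r} is not a non-negative integer "
            f"(protein {raw.index[i]}, sample {raw.columns[j]})"
        )
    counts = numeric.astype(np.int64)

    smap = pd.read_csv(group_map_path, sep="\t", dtype=str)
    if "sample" not in smap.columns or "group" not in smap.columns:
        raise ParseError("sample map must have 'sample' and 'group' columns")
    smap = smap.set_index("sample")
    groups = smap["group"]
    cases = smap["case"] if "case" in smap.columns else pd.Series(
        smap.index, index=smap.index, name="case"
    )
    return SpectralCountMatrix(counts, groups, cases)


def write_count_table(
    matrix: SpectralCountMatrix, path: str | Path, group_map_path: str | Path
) -> None:
    matrix.counts.to_csv(path, sep="\t", index_label="accession")
    smap = pd.DataFrame(
        {
            "sample": matrix.counts.columns,
            "group": [matrix.groups[s] for s in matrix.counts.columns],
            "case": [matrix.cases[s] for s in matrix.counts.columns],
        }
    )
    smap.to_csv(group_map_path, sep="\t", index=False)


def lengths_from_fasta(path: str | Path) -> ProteinAnnotationTable:
    """Derive protein lengths from a FASTA file.

    The accession is the first whitespace-delimited token of the header;
    the rest of the header becomes the description.  Length counts residues
    only — gap (``-``, ``.``) and stop (``*``) characters are excluded.
    """
    rows: dict[str, tuple[int, str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        acc = rec.id
        if acc in rows:
            raise ParseError(f"duplicate accession {acc!r} in FASTA")
        seq = str(rec.seq).replace("-", "").replace(".", "").replace("*", "")
        if not seq:
            raise ParseError(f"empty sequence for accession {acc!r}")
        rows[acc] = (len(seq), acc, rec.description)
    if not rows:
        raise ParseError(f"no FASTA records in {path}")
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["length", "symbol", "description"]
    )
    table.index.name = "accession"
    return ProteinAnnotationTable(table)


def read_annotation_table(path: str | Path) -> ProteinAnnotationTable:
    """Read a TSV annotation table with columns accession, length, symbol."""
    t = pd.read_csv(path, sep="\t", dtype={"accession": str, "symbol": str})
    if "accession" not in t.columns or "length" not in t.columns:
        raise ParseError("annotation table must have 'accession' and 'length' columns")
    t = t.set_index("accession")
    if "symbol" not in t.columns:
        t["symbol"] = t.index
    if "description" not in t.columns:
        t["description"] = ""
    lengths = pd.to_numeric(t["length"], errors="coerce")
    if lengths.isna().any() or (lengths != lengths.round()).any():
        bad = t.index[lengths.isna() | (lengths != lengths.round())][0]
        raise ParseError(f"non-integer length for accession {bad!r}")
    t["length"] = lengths.astype(np.int64)
    return ProteinAnnotationTable(t[["length", "symbol", "description"]])


def write_annotation_table(ann: ProteinAnnotationTable, path: str | Path) -> None:
    ann.table.to_csv(path, sep="\t", index_label="accession")


def read_cohort(path: str | Path) -> CohortTable:
    """Read and validate a cohort CSV (header contract in COHORT_BASE_COLUMNS)."""
    p = Path(path)
    if p.stat().st_size == 0:
        raise ParseError(f"empty cohort file: {path}")
    t = pd.read_csv(p)
    if len(t) == 0:
        raise ParseError(f"cohort file has a header but no rows: {path}")
    return CohortTable(t)


def write_cohort(cohort: CohortTable, path: str | Path) -> None:
    cohort.table.to_csv(path, index=False)


def write_report(results: dict, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write analysis results as TSV tables plus one JSON summary.

    ``results`` maps names to DataFrames (written as ``<stem>_<name>.tsv``)
    or to JSON-serialisable objects (collected into ``<stem>_summary.json``).
    Returns the paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    summary: dict = {}
    for name, obj in results.items():
        if isinstance(obj, pd.DataFrame):
            p = out / f"{stem}_{name}.tsv"
            obj.to_csv(p, sep="\t", index=False)
            written[name] = p
        else:
            summary[name] = obj
    if summary:
        p = out / f"{stem}_summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=2, default=_json_default)
        written["summary"] = p
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serialisable: {type(o)}")
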