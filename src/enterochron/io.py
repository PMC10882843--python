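"""Reading, validation and joining of study tables.

All tabular inputs are UTF-8 tab-separated files with one header row. The
canonical in-memory orientation of count tables is samples-as-rows; a file
stored taxa-as-rows is transposed on read. Missing count cells are illegal:
absence of a taxon must be encoded as an explicit zero upstream, because the
count models downstream require complete matrices.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ALLOWED_AGES",
    "STAGE_BY_AGE",
    "CountTable",
    "SampleRecord",
    "AnalysisDataset",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "read_amr_table",
    "read_qpcr_table",
    "assemble_dataset",
]

#: The nine sampling ages (weeks) of the cohort design, from nursery entry
#: through estrus/AI, parturition and weaning of the first litter.
ALLOWED_AGES: tuple[int, ...] = (3, 6, 10, 12, 22, 32, 49, 50, 53)

#: Physiological stage implied by sampling age; every age not listed is a
#: growing-phase sample.
STAGE_BY_AGE: dict[int, str] = {
    32: "estrus",
    49: "pre_parturition",
    50: "parturition",
    53: "weaning",
}

STAGES = ("growing", "estrus", "pre_parturition", "parturition", "weaning")


def stage_for_age(age_weeks: float) -> str:
    """Physiological stage label for a sampling age in weeks."""
    return STAGE_BY_AGE.get(int(age_weeks), "growing")


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: dict[str, int] = {}
    for lab in labels:
        seen[lab] = seen.get(lab, 0) + 1
    dups = [lab for lab, k in seen.items() if k > 1]
    if dups:
        raise ValueError(f"duplicate {what} label(s): {', '.join(sorted(dups))}")


@dataclasses.dataclass
class CountTable:
    """A samples x taxa matrix of nonnegative integer counts.

    Parameters
    ----------
    sample_ids
        Row labels, unique.
    taxon_ids
        Column labels, unique.
    counts
        Integer array of shape ``(n_samples, n_taxa)`` with no negative
        entries.
    taxonomy
        Optional lineage string per taxon (same length as ``taxon_ids``).
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray
    taxonomy: list[str] | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n, s = self.counts.shape
        if n != len(self.sample_ids) or s != len(self.taxon_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}"
            )
        if self.taxonomy is not None and len(self.taxonomy) != len(self.taxon_ids):
            raise ValueError("taxonomy length does not match taxon_ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.taxon_ids
        )

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; all-zero samples yield all-zero rows."""
        tot = self.counts.sum(axis=1, keepdims=True).astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            ra = np.where(tot > 0, self.counts / np.where(tot > 0, tot, 1.0), 0.0)
        return pd.DataFrame(ra, index=self.sample_ids, columns=self.taxon_ids)

    def select_samples(self, sample_ids: Iterable[str]) -> "CountTable":
        wanted = list(sample_ids)
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in wanted if s not in idx]
        if missing:
            raise KeyError(f"unknown sample id(s): {', '.join(missing)}")
        rows = [idx[s] for s in wanted]
        return CountTable(
            sample_ids=wanted,
            taxon_ids=list(self.taxon_ids),
            counts=self.counts[rows],
            taxonomy=list(self.taxonomy) if self.taxonomy is not None else None,
        )


@dataclasses.dataclass
class SampleRecord:
    """Metadata for one fecal sample: one pig at one sampling age."""

    sample_id: str
    pig_id: str
    cohort: int
    age_weeks: float
    stage: str = ""
    microbiome_subset: bool = False
    raw_read_count: int | None = None

    def __post_init__(self) -> None:
        if self.cohort not in (1, 2):
            raise ValueError(
                f"sample {self.sample_id!r}: cohort must be 1 or 2, got {self.cohort}"
            )
        if not self.stage:
            self.stage = stage_for_age(self.age_weeks)
        if self.stage not in STAGES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown stage {self.stage!r}"
            )
        expected = stage_for_age(self.age_weeks)
        if int(self.age_weeks) in STAGE_BY_AGE or self.stage != expected:
            if self.stage != expected:
                raise ValueError(
                    f"sample {self.sample_id!r}: stage {self.stage!r} is "
                    f"inconsistent with age {self.age_weeks} (expected {expected!r})"
                )
        if self.raw_read_count is not None and self.raw_read_count < 0:
            raise ValueError(
                f"sample {self.sample_id!r}: raw_read_count must be nonnegative"
            )


@dataclasses.dataclass
class AnalysisDataset:
    """Joined analysis inputs with cross-references enforced.

    ``amr`` and ``qpcr`` rows may reference metadata-only samples (the plate
    count panel covers all pigs while microbiome profiling covers a subset),
    but every count-table sample must have a metadata record.
    """

    counts: CountTable
    metadata: list[SampleRecord]
    amr: pd.DataFrame | None = None
    qpcr: pd.DataFrame | None = None

    def metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(r) for r in self.metadata])


def read_count_table(
    path: str | Path,
    orientation: Literal["samples_as_rows", "taxa_as_rows"] = "samples_as_rows",
) -> CountTable:
    """Read a TSV count table, returning samples-as-rows regardless of the
    on-disk orientation.

    The file must have one header row of labels and a leading label column.
    Cells must be nonnegative integers; violations raise ``ValueError``
    naming the offending coordinates.
    """
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique(header[1:], "column")  # pandas would silently rename these
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    row_labels = [str(x) for x in df.index]
    col_labels = [str(x) for x in df.columns]
    _check_unique(row_labels, "row")
    _check_unique(col_labels, "column")
    mat = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                val = int(cell)
                if float(cell) != val:
                    raise ValueError
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-integer count {cell!r} at row {row_labels[i]!r}, "
                    f"column {col_labels[j]!r} in {path}"
                ) from None
            if val < 0:
                raise ValueError(
                    f"negative count {val} at row {row_labels[i]!r}, "
                    f"column {col_labels[j]!r} in {path}"
                )
            mat[i, j] = val
    if orientation == "taxa_as_rows":
        return CountTable(sample_ids=col_labels, taxon_ids=row_labels, counts=mat.T)
    if orientation != "samples_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return CountTable(sample_ids=row_labels, taxon_ids=col_labels, counts=mat)


def write_count_table(table: CountTable, path: str | Path) -> None:
    """Write a CountTable as samples-as-rows TSV (first column `sample_id`)."""
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_metadata(path: str | Path, strict_ages: bool = True) -> list[SampleRecord]:
    """Read and validate sample metadata.

    Required columns: sample_id, pig_id, cohort, age_weeks. Optional: stage
    (auto-derived from age when absent), microbiome_subset, raw_read_count.
    With ``strict_ages`` (default) ages must lie on the study's nine-point
    grid; disable to admit arbitrary age grids.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    required = ["sample_id", "pig_id", "cohort", "age_weeks"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"metadata missing required column(s): {', '.join(missing)}")
    records: list[SampleRecord] = []
    seen: set[tuple[str, float]] = set()
    for _, row in df.iterrows():
        age = float(row["age_weeks"])
        if strict_ages and age not in ALLOWED_AGES:
            raise ValueError(
                f"sample {row['sample_id']!r}: age {age} not on the study age "
                f"grid {list(ALLOWED_AGES)}; pass strict_ages=False to allow"
            )
        key = (str(row["pig_id"]), age)
        if key in seen:
            raise ValueError(f"duplicate (pig_id, age_weeks) record: {key}")
        seen.add(key)
        stage = str(row["stage"]) if "stage" in df.columns and pd.notna(row.get("stage")) else ""
        subset_raw = row.get("microbiome_subset") if "microbiome_subset" in df.columns else None
        subset = str(subset_raw).strip().lower() in ("1", "true", "yes") if pd.notna(subset_raw) else False
        rrc_raw = row.get("raw_read_count") if "raw_read_count" in df.columns else None
        rrc = int(float(rrc_raw)) if rrc_raw is not None and pd.notna(rrc_raw) and str(rrc_raw) != "" else None
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]),
                pig_id=str(row["pig_id"]),
                cohort=int(float(row["cohort"])),
                age_weeks=age,
                stage=stage,
                microbiome_subset=subset,
                raw_read_count=rrc,
            )
        )
    _check_unique([r.sample_id for r in records], "sample")
    return records


def write_metadata(records: Sequence[SampleRecord], path: str | Path) -> None:
    df = pd.DataFrame([dataclasses.asdict(r) for r in records])
    df.to_csv(path, sep="\t", index=False)


AMR_COLUMNS = ["sample_id", "bacterium", "drug", "drug_class", "log10_cfu_per_g"]
QPCR_COLUMNS = ["sample_id", "gene", "copies_per_g"]


def read_amr_table(path: str | Path) -> pd.DataFrame:
    """Read the plate-count table. Empty log10_cfu_per_g cells mean no growth
    on that antimicrobial plate and are kept as NaN."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in AMR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AMR table missing column(s): {', '.join(missing)}")
    df["log10_cfu_per_g"] = pd.to_numeric(df["log10_cfu_per_g"], errors="raise")
    return df[AMR_COLUMNS].copy()


def read_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read the qPCR copy-number table (linear copies per gram of feces)."""
    df = pd.read_csv(path, sep="\t", header=0)
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing column(s): {', '.join(missing)}")
    df["copies_per_g"] = pd.to_numeric(df["copies_per_g"], errors="raise")
    if (df["copies_per_g"] < 0).any():
        bad = df.loc[df["copies_per_g"] < 0, "sample_id"].iloc[0]
        raise ValueError(f"negative copy number for sample {bad!r}")
    return df[QPCR_COLUMNS].copy()


def assemble_dataset(
    counts: CountTable,
    metadata: Sequence[SampleRecord],
    amr: pd.DataFrame | None = None,
    qpcr: pd.DataFrame | None = None,
) -> AnalysisDataset:
    """Join inputs into one dataset, enforcing cross-references.

    Every count-table sample must resolve to metadata; AMR/qPCR rows must
    also resolve, though metadata-only samples (no sequencing) are fine.
    """
    known = {r.sample_id for r in metadata}
    orphans = [s for s in counts.sample_ids if s not in known]
    if orphans:
        raise ValueError(
            f"count-table sample(s) missing from metadata: {', '.join(orphans)}"
        )
    for name, tab in (("AMR", amr), ("qPCR", qpcr)):
        if tab is not None:
            bad = sorted(set(tab["sample_id"].astype(str)) - known)
            if bad:
                raise ValueError(
                    f"{name} table references unknown sample(s): {', '.join(bad)}"
                )
    return AnalysisDataset(counts=counts, metadata=list(metadata), amr=amr, qpcr=qpcr)
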