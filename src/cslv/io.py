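"""Reading and writing array-data tables: marker manifests, LRR matrices,
phenotype/cohort tables and CSLV feature tables.

All on-disk formats are TSV. Coordinates in files are 1-based inclusive,
the standard for array manifests. The long LRR dialect mirrors Illumina
GenomeStudio "final report" columns (Sample ID, SNP Name, Log R Ratio)
with a configurable number of header lines to skip.

In memory:

* a marker manifest is a :class:`MarkerManifest` (a validated, sorted
  ``DataFrame`` plus drop counts);
* an LRR matrix is a ``DataFrame`` with sample ids as the index and
  marker ids as columns, ordered by manifest order (chromosome, then
  position, ties by marker id);
* a cohort table is a ``DataFrame`` with columns ``sample_id``,
  ``label`` (1 = case, 0 = control), ``age`` and ``group``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBuild, default_build

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerManifest",
    "read_manifest",
    "write_manifest",
    "read_lrr",
    "write_lrr",
    "read_phenotypes",
    "write_phenotypes",
    "read_cslv",
    "write_cslv",
    "validate_dataset",
]

_SEX_CHROM_NAMES = {"x", "y", "xy", "23", "24", "25"}

_LONG_COLUMN_ALIASES = {
    "sample id": "sample_id",
    "snp name": "marker_id",
    "log r ratio": "lrr",
}

_NA_TOKENS = {"", "na", "nan", "null", "."}


@dataclass(frozen=True)
class MarkerManifest:
    """Validated marker locations, sorted by (chromosome, position, marker_id).

    ``dropped_sex`` and ``dropped_out_of_range`` count records removed
    during validation; sex chromosomes never enter a CSLV analysis.
    """

    table: pd.DataFrame  # columns: marker_id, chromosome, position
    build: GenomeBuild
    dropped_sex: int = 0
    dropped_out_of_range: int = 0

    @property
    def marker_ids(self) -> pd.Index:
        return pd.Index(self.table["marker_id"].to_numpy(), name=None)

    def __len__(self) -> int:
        return len(self.table)


def _normalise_chromosome(name: str) -> str:
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


def _sort_manifest(df: pd.DataFrame, build: GenomeBuild) -> pd.DataFrame:
    order = {name: i for i, name in enumerate(build.names)}
    df = df.assign(_ord=df["chromosome"].map(order))
    df = df.sort_values(["_ord", "position", "marker_id"], kind="mergesort")
    return df.drop(columns="_ord").reset_index(drop=True)


def read_manifest(path, build: GenomeBuild | None = None) -> MarkerManifest:
    """Read and validate a marker manifest TSV.

    The file needs header columns ``marker_id``, ``chromosome`` and
    ``position`` (1-based bp). Sex-chromosome records and records whose
    position exceeds the chromosome length are dropped with logged
    counts; a position below 1 or a duplicate marker id is a hard error
    naming the offending row.
    """
    build = build or default_build()
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"marker_id", "chromosome", "position"} - set(df.columns)
    if missing:
        raise ValueError(f"manifest missing columns: {sorted(missing)}")

    positions = pd.to_numeric(df["position"], errors="coerce")
    bad = positions.isna() | (positions != positions.round())
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(
            f"manifest row {row + 2}: unparseable position {df['position'].iloc[row]!r}"
        )
    df = df.assign(
        position=positions.astype(np.int64),
        chromosome=df["chromosome"].map(_normalise_chromosome),
    )

    below_one = df["position"] < 1
    if below_one.any():
        row = int(np.flatnonzero(below_one.to_numpy())[0])
        raise ValueError(
            f"manifest row {row + 2}: position {df['position'].iloc[row]} "
            "violates 1-based coordinates"
        )

    dup = df["marker_id"].duplicated()
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValueError(
            f"manifest row {row + 2}: duplicate marker_id {df['marker_id'].iloc[row]!r}"
        )

    is_sex = df["chromosome"].str.lower().isin(_SEX_CHROM_NAMES)
    dropped_sex = int(is_sex.sum())
    df = df[~is_sex]

    lengths = df["chromosome"].map(build.chromosomes)
    unknown = lengths.isna()
    out_of_range = unknown | (df["position"] > lengths.fillna(0).astype(np.int64))
    dropped_oor = int(out_of_range.sum())
    df = df[~out_of_range]

    if dropped_sex:
        logger.info("manifest: dropped %d sex-chromosome marker(s)", dropped_sex)
    if dropped_oor:
        logger.info(
            "manifest: dropped %d marker(s) outside the genome build", dropped_oor
        )

    return MarkerManifest(
        table=_sort_manifest(df[["marker_id", "chromosome", "position"]], build),
        build=build,
        dropped_sex=dropped_sex,
        dropped_out_of_range=dropped_oor,
    )


def write_manifest(manifest: MarkerManifest, path) -> None:
    manifest.table.to_csv(path, sep="\t", index=False)


def _parse_lrr_values(raw: pd.Series, context: str) -> pd.Series:
    cleaned = raw.astype(str).str.strip()
    is_na = cleaned.str.lower().isin(_NA_TOKENS) | raw.isna()
    values = pd.to_numeric(cleaned.where(~is_na), errors="coerce")
    bad = values.isna() & ~is_na
    if bad.any():
        offender = cleaned[bad].iloc[0]
        raise ValueError(f"{context}: non-numeric LRR value {offender!r}")
    return values.astype(float)


def _check_missingness(matrix: pd.DataFrame, max_missing_fraction: float) -> None:
    frac = float(matrix.isna().to_numpy().mean()) if matrix.size else 0.0
    if frac > max_missing_fraction:
        raise ValueError(
            f"LRR matrix is {frac:.1%} missing, above the "
            f"{max_missing_fraction:.0%} ceiling"
        )


def read_lrr(
    path,
    manifest: MarkerManifest,
    dialect: str = "wide",
    skip_header_lines: int = 0,
    max_missing_fraction: float = 0.2,
) -> pd.DataFrame:
    """Read an LRR matrix, aligned to manifest marker order.

    ``dialect="wide"`` expects one row per sample with a ``sample_id``
    column followed by one column per marker. ``dialect="long"`` expects
    columns (sample_id, marker_id, lrr), accepting the Illumina final
    report spellings. Markers absent from the manifest are dropped with
    a logged count; duplicate (sample, marker) pairs in the long dialect
    are an error; empty/NA tokens become missing values.
    """
    if dialect == "wide":
        df = pd.read_csv(path, sep="\t", dtype=str, skiprows=skip_header_lines)
        if "sample_id" not in df.columns:
            raise ValueError("wide LRR file missing a sample_id column")
        if df["sample_id"].duplicated().any():
            raise ValueError("wide LRR file has duplicate sample ids")
        df = df.set_index("sample_id")
        df.index.name = None
        known = [c for c in df.columns if c in set(manifest.marker_ids)]
        n_dropped = df.shape[1] - len(known)
        if n_dropped:
            logger.warning(
                "LRR matrix: dropped %d column(s) not in the manifest", n_dropped
            )
        matrix = df[known].apply(lambda col: _parse_lrr_values(col, f"column {col.name}"))
    elif dialect == "long":
        df = pd.read_csv(path, sep="\t", dtype=str, skiprows=skip_header_lines)
        df.columns = [
            _LONG_COLUMN_ALIASES.get(str(c).strip().lower(), str(c).strip().lower())
            for c in df.columns
        ]
        missing = {"sample_id", "marker_id", "lrr"} - set(df.columns)
        if missing:
            raise ValueError(f"long LRR file missing columns: {sorted(missing)}")
        dup = df.duplicated(subset=["sample_id", "marker_id"])
        if dup.any():
            pair = df.loc[dup, ["sample_id", "marker_id"]].iloc[0]
            raise ValueError(
                f"long LRR file repeats entry ({pair['sample_id']}, {pair['marker_id']})"
            )
        df["lrr"] = _parse_lrr_values(df["lrr"], "long LRR file")
        known_mask = df["marker_id"].isin(set(manifest.marker_ids))
        n_dropped = int(df.loc[~known_mask, "marker_id"].nunique())
        if n_dropped:
            logger.warning(
                "LRR matrix: dropped %d marker(s) not in the manifest", n_dropped
            )
        df = df[known_mask]
        matrix = df.pivot(index="sample_id", columns="marker_id", values="lrr")
        # preserve first-appearance sample order; never silently reorder
        matrix = matrix.reindex(df["sample_id"].drop_duplicates())
        matrix.index.name = None
        matrix.columns.name = None
    else:
        raise ValueError(f"unknown LRR dialect {dialect!r}")

    ordered = [m for m in manifest.marker_ids if m in matrix.columns]
    matrix = matrix[ordered].astype(float)
    _check_missingness(matrix, max_missing_fraction)
    return matrix


def write_lrr(matrix: pd.DataFrame, path) -> None:
    """Write an LRR matrix in the wide dialect (missing written as NA)."""
    out = matrix.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


_LABEL_TOKENS = {
    "case": 1, "control": 0, "1": 1, "0": 0,
    "true": 1, "false": 0, "yes": 1, "no": 0,
}


def read_phenotypes(path) -> pd.DataFrame:
    """Read a phenotype table: sample_id, label (case/control), age, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "label", "age"} - set(df.columns)
    if missing:
        raise ValueError(f"phenotype table missing columns: {sorted(missing)}")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes[:5]}")
    labels = df["label"].str.strip().str.lower().map(_LABEL_TOKENS)
    if labels.isna().any():
        bad = df.loc[labels.isna(), "label"].iloc[0]
        raise ValueError(f"unrecognised label {bad!r} (expected case/control)")
    ages = pd.to_numeric(df["age"], errors="coerce")
    if ages.isna().any() or (ages < 0).any():
        raise ValueError("ages must be non-negative numbers")
    group = df["group"].fillna("unknown") if "group" in df.columns else "unknown"
    return pd.DataFrame(
        {
            "sample_id": df["sample_id"],
            "label": labels.astype(int),
            "age": ages.astype(float),
            "group": group,
        }
    )


def write_phenotypes(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["label"] = np.where(out["label"].astype(int) == 1, "case", "control")
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_cslv(table: pd.DataFrame, path) -> None:
    """Write a CSLV feature table: sample_id then ``<chrom>_seg<i>`` columns."""
    out = table.copy()
    out.insert(0, "sample_id", out.index)
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def read_cslv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str}, na_values=["NA"])
    if "sample_id" not in df.columns:
        raise ValueError("CSLV table missing a sample_id column")
    df = df.set_index("sample_id")
    df.index.name = None
    return df.astype(float)


def validate_dataset(
    manifest: MarkerManifest,
    lrr: pd.DataFrame,
    cohort: pd.DataFrame | None = None,
) -> dict:
    """Cross-check manifest, LRR matrix and (optionally) phenotypes.

    Returns a summary dict; raises on inconsistency.
    """
    unknown = [m for m in lrr.columns if m not in set(manifest.marker_ids)]
    if unknown:
        raise ValueError(f"LRR matrix has markers absent from manifest: {unknown[:5]}")
    report = {
        "n_markers": int(lrr.shape[1]),
        "n_samples": int(lrr.shape[0]),
        "n_manifest_markers": len(manifest),
        "missing_fraction": float(lrr.isna().to_numpy().mean()) if lrr.size else 0.0,
        "dropped_sex_markers": manifest.dropped_sex,
        "dropped_out_of_range_markers": manifest.dropped_out_of_range,
    }
    if cohort is not None:
        absent = set(cohort["sample_id"]) - set(lrr.index)
        if absent:
            raise ValueError(
                f"{len(absent)} cohort sample(s) missing from LRR matrix, "
                f"e.g. {sorted(absent)[:5]}"
            )
        report["n_cases"] = int((cohort["label"] == 1).sum())
        report["n_controls"] = int((cohort["label"] == 0).sum())
    return report
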