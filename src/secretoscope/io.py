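"""Readers and writers for the pipeline's external formats.

Formats: MaxQuant-style wide peptide TSV (``Sequence``, ``Proteins``,
one ``Intensity <sample>`` column per sample), a generic long-format
peptide TSV, GMT gene-set files, the design TSV, category maps,
immunoassay CSVs, and TSV/JSON result bundles.

All readers validate strictly and raise :class:`FormatError` naming the
offending column/line rather than silently coercing. Intensity zeros are
converted to missing on read: an MS1 intensity of zero is the search
engine's encoding of "not observed".
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import (
    AssayTable,
    CategoryMap,
    DataError,
    GeneSetCollection,
    PeptideTable,
    SampleDesign,
)

logger = logging.getLogger(__name__)

INTENSITY_PREFIX = "Intensity "


class FormatError(DataError):
    """A file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# peptide tables
# ---------------------------------------------------------------------------

def read_peptide_table(path: str | Path, dialect: str = "auto") -> PeptideTable:
    """Read a raw-scale peptide intensity table.

    ``dialect='wide'`` expects MaxQuant peptides.txt columns
    (``Sequence``, ``Proteins``, ``Intensity <sample>``...);
    ``dialect='long'`` expects columns ``protein``, ``sequence``,
    ``sample``, ``intensity``. ``'auto'`` sniffs the header.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if dialect == "auto":
        dialect = "wide" if "Sequence" in df.columns else "long"
    if dialect == "wide":
        return _parse_wide(df, path)
    if dialect == "long":
        return _parse_long(df, path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _to_float(series: pd.Series, path: Path, col: str) -> np.ndarray:
    out = pd.to_numeric(series, errors="coerce")
    bad = out.isna() & series.notna() & (series.str.strip() != "")
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise FormatError(
            f"{path.name}: non-numeric intensity {series.iloc[row]!r} "
            f"in column {col!r}, data row {row}"
        )
    return out.to_numpy(dtype=float)


def _parse_wide(df: pd.DataFrame, path: Path) -> PeptideTable:
    for col in ("Sequence", "Proteins"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: mandatory column {col!r} missing")
    int_cols = [c for c in df.columns if c.startswith(INTENSITY_PREFIX)]
    if not int_cols:
        raise FormatError(
            f"{path.name}: no '{INTENSITY_PREFIX}<sample>' columns found"
        )
    key = pd.MultiIndex.from_arrays(
        [df["Proteins"], df["Sequence"]], names=["protein", "sequence"]
    )
    if key.duplicated().any():
        dupes = sorted({seq for _, seq in key[key.duplicated()]})[:5]
        raise FormatError(
            f"{path.name}: duplicated peptide row(s) for sequence(s) {dupes}"
        )
    mat = np.column_stack([_to_float(df[c], path, c) for c in int_cols])
    mat[mat == 0] = np.nan  # zero encodes "not observed"
    samples = [c[len(INTENSITY_PREFIX):] for c in int_cols]
    frame = pd.DataFrame(mat, index=key, columns=samples)
    return PeptideTable(frame, is_log2=False)


def _parse_long(df: pd.DataFrame, path: Path) -> PeptideTable:
    for col in ("protein", "sequence", "sample", "intensity"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: mandatory column {col!r} missing")
    vals = _to_float(df["intensity"], path, "intensity")
    df = df.assign(intensity=vals)
    dup = df.duplicated(subset=["protein", "sequence", "sample"])
    if dup.any():
        seqs = sorted(df.loc[dup, "sequence"].unique())[:5]
        raise FormatError(
            f"{path.name}: duplicated (peptide, sample) row(s) for {seqs}"
        )
    wide = df.pivot(index=["protein", "sequence"], columns="sample", values="intensity")
    wide.columns.name = None
    mat = wide.to_numpy()
    mat[mat == 0] = np.nan
    frame = pd.DataFrame(mat, index=wide.index, columns=list(wide.columns))
    return PeptideTable(frame, is_log2=False)


def write_peptide_table(table: PeptideTable, path: str | Path) -> None:
    """Write a raw-scale table in the wide (MaxQuant-like) dialect.

    Missing cells are serialized as 0, matching the convention the reader
    undoes.
    """
    if table.is_log2:
        raise DataError("write_peptide_table expects a raw-scale table")
    idx = table.intensities.index
    out = pd.DataFrame(
        {
            "Sequence": idx.get_level_values("sequence"),
            "Proteins": idx.get_level_values("protein"),
        }
    )
    for s in table.sample_ids:
        out[INTENSITY_PREFIX + s] = table.intensities[s].fillna(0.0).to_numpy()
    out.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def read_design(path: str | Path, reference: str | None = None) -> SampleDesign:
    """Read the sample design TSV (``sample donor condition batch``).

    The reference condition comes either from a boolean ``reference``
    column in the file or from the ``reference`` argument.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample", "donor", "condition", "batch"):
        if col not in df.columns:
            raise FormatError(f"{path.name}: mandatory column {col!r} missing")
    df = df.set_index("sample")
    if reference is None:
        if "reference" not in df.columns:
            raise FormatError(
                f"{path.name}: no 'reference' column and no reference given; "
                "pass --reference <condition>"
            )
        flagged = df.loc[
            df["reference"].str.lower().isin({"1", "true", "yes"}), "condition"
        ].unique()
        if len(flagged) != 1:
            raise FormatError(
                f"{path.name}: exactly one condition must be flagged reference, "
                f"found {sorted(flagged)}"
            )
        reference = flagged[0]
    return SampleDesign(df[["donor", "condition", "batch"]], reference=reference)


def write_design(design: SampleDesign, path: str | Path) -> None:
    df = design.frame.copy()
    df["reference"] = (df["condition"] == design.reference).map(
        {True: "true", False: "false"}
    )
    df.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``name<TAB>description<TAB>member...`` per line."""
    path = Path(path)
    collection = GeneSetCollection({})
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path.name}:{lineno}: GMT line needs >=3 tab-separated "
                    f"fields, got {len(fields)}"
                )
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path.name}:{lineno}: set {name!r} is empty")
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                logger.warning(
                    "%s:%d: duplicate members in set %r deduplicated",
                    path.name,
                    lineno,
                    name,
                )
            collection.add(name, unique, desc)
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in collection.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


# ---------------------------------------------------------------------------
# category map
# ---------------------------------------------------------------------------

def read_category_map(path: str | Path) -> CategoryMap:
    """Two-column TSV: protein id, category label."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path.name}: expected two columns (protein, category)")
    df.columns = ["protein", "category"] + list(df.columns[2:])
    return CategoryMap(dict(zip(df["protein"], df["category"])))


def write_category_map(cmap: CategoryMap, path: str | Path) -> None:
    pd.DataFrame(
        sorted(cmap.mapping.items()), columns=["protein", "category"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# immunoassay
# ---------------------------------------------------------------------------

def read_assay(measurements_path: str | Path, samples_path: str | Path) -> AssayTable:
    """Read the plate long-format CSV and the per-sample DNA/metadata CSV."""
    mpath, spath = Path(measurements_path), Path(samples_path)
    meas = pd.read_csv(mpath)
    for col in ("analyte", "sample", "concentration"):
        if col not in meas.columns:
            raise FormatError(f"{mpath.name}: mandatory column {col!r} missing")
    if "detected" not in meas.columns:
        meas["detected"] = meas["concentration"] > 0
    else:
        meas["detected"] = meas["detected"].astype(bool)
    samp = pd.read_csv(spath)
    for col in ("sample", "donor", "condition", "dna"):
        if col not in samp.columns:
            raise FormatError(f"{spath.name}: mandatory column {col!r} missing")
    return AssayTable(meas, samp.set_index("sample"))


def write_assay(assay: AssayTable, measurements_path: str | Path, samples_path: str | Path) -> None:
    assay.measurements.to_csv(measurements_path, index=False)
    assay.samples.to_csv(samples_path, index_label="sample")


# ---------------------------------------------------------------------------
# result bundles
# ---------------------------------------------------------------------------

def config_hash(config: Mapping) -> str:
    """Stable short hash of a JSON-serializable configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_results(
    tables: Mapping[str, pd.DataFrame],
    out_dir: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict[str, Path]:
    """Write each table as ``<name>.tsv`` plus a run-metadata JSON.

    The metadata records the config hash (which regenerates the inputs
    for simulated runs), the seed, and library versions.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, df in tables.items():
        p = out_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        written[name] = p
    meta = {
        "config_hash": config_hash(config) if config is not None else None,
        "config": dict(config) if config is not None else None,
        "seed": seed,
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "tables": sorted(tables),
    }
    meta_path = out_dir / "run_metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    written["run_metadata"] = meta_path
    return written
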