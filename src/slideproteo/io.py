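"""Readers and writers for the pipeline's tabular artifacts.

All tables are plain TSV (tab separator, ``.`` decimal, no quoting, empty
string = missing, UTF-8); lines starting with ``#`` are provenance
headers written by the pipeline and are skipped on read. Gene sets use
the MSigDB GMT convention. Every reader validates structure and returns
typed objects so downstream stages never touch raw files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import FormatError

logger = logging.getLogger(__name__)

#: required columns of a precursor-level long table
PRECURSOR_COLUMNS = ("sample_id", "protein", "peptide_id", "ms1_area")

#: controlled vocabularies for the sample metadata table
META_ENUMS: Mapping[str, tuple[str, ...]] = {
    "cohort": ("single_slide", "multi_section"),
    "biopsy_type": ("core", "forceps", "cryo", "surgical"),
    "histology": ("AC", "SCC", "other", "unknown"),
    "pdl1_status": ("positive", "negative", "unknown"),
    "instrument": ("astral", "timstof", "exploris"),
}


@dataclass(frozen=True)
class SignatureDefinition:
    """A named gene list (signature, marker panel or protein complex).

    Genes are stored uppercase and deduplicated in first-seen order.
    """

    name: str
    genes: tuple[str, ...]
    source: str = ""

    def __post_init__(self) -> None:
        seen: dict[str, None] = {}
        for g in self.genes:
            gu = str(g).strip().upper()
            if gu:
                seen.setdefault(gu, None)
        if not seen:
            raise FormatError(f"signature {self.name!r} has no genes")
        object.__setattr__(self, "genes", tuple(seen))

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene: str) -> bool:
        return str(gene).upper() in set(self.genes)


# ---------------------------------------------------------------------------
# precursor table


def validate_precursor_table(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a precursor long table already held in memory."""
    missing = [c for c in PRECURSOR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"precursor table missing column(s): {', '.join(missing)}")
    dup = table.duplicated(subset=["sample_id", "peptide_id"])
    if dup.any():
        first = table.loc[dup.idxmax(), ["sample_id", "peptide_id"]]
        raise FormatError(
            "duplicate (sample_id, peptide_id) pair: "
            f"({first['sample_id']}, {first['peptide_id']})"
        )
    return table


def read_precursor_table(path: str | Path) -> pd.DataFrame:
    """Read a precursor-level long table.

    Rows with non-positive ``ms1_area`` are dropped (a detected precursor
    must carry positive signal); the number removed is logged.
    """
    table = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        dtype={"sample_id": str, "protein": str, "peptide_id": str},
    )
    missing = [c for c in PRECURSOR_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(
            f"{path}: precursor table missing column(s): {', '.join(missing)}"
        )
    table["ms1_area"] = pd.to_numeric(table["ms1_area"], errors="coerce")
    bad = ~(table["ms1_area"] > 0)
    if bad.any():
        logger.warning("%s: dropped %d rows with non-positive ms1_area", path, bad.sum())
        table = table.loc[~bad].reset_index(drop=True)
    if "detected" not in table.columns:
        table["detected"] = True
    return validate_precursor_table(table)


def write_precursor_table(table: pd.DataFrame, path: str | Path, header: str = "") -> None:
    _write_tsv(table, path, header, index=False)


# ---------------------------------------------------------------------------
# protein quantification matrix


def read_quant_matrix(path: str | Path, imputed: bool = False) -> pd.DataFrame:
    """Read a protein x sample quantification matrix (linear scale).

    The first column holds gene-centric protein symbols; the remaining
    columns are samples. ``imputed=True`` asserts completeness.
    """
    matrix = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    matrix.index = matrix.index.astype(str)
    if matrix.index.has_duplicates:
        raise FormatError(f"{path}: duplicate protein rows")
    if matrix.columns.has_duplicates:
        raise FormatError(f"{path}: duplicate sample columns")
    values = matrix.to_numpy(dtype=float)
    if np.nanmin(values, initial=0.0) < 0:
        raise FormatError(f"{path}: negative abundances")
    if imputed and np.isnan(values).any():
        n = int(np.isnan(values).sum())
        raise FormatError(f"{path}: imputed matrix contains {n} missing cell(s)")
    return matrix


def write_quant_matrix(matrix: pd.DataFrame, path: str | Path, header: str = "") -> None:
    _write_tsv(matrix, path, header, index=True, index_label="protein")


# ---------------------------------------------------------------------------
# TIC traces


def read_tic_traces(path: str | Path) -> pd.DataFrame:
    """Read long-format total-ion-chromatogram traces.

    Columns: ``sample_id``, ``time_min`` (strictly increasing within a
    sample), ``intensity`` (non-negative).
    """
    tic = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    for col in ("sample_id", "time_min", "intensity"):
        if col not in tic.columns:
            raise FormatError(f"{path}: TIC table missing column {col!r}")
    for sid, grp in tic.groupby("sample_id", sort=False):
        t = grp["time_min"].to_numpy(float)
        if np.any(np.diff(t) <= 0):
            raise FormatError(f"{path}: time not strictly increasing for sample {sid}")
        if (grp["intensity"].to_numpy(float) < 0).any():
            raise FormatError(f"{path}: negative intensity for sample {sid}")
    return tic


def write_tic_traces(tic: pd.DataFrame, path: str | Path, header: str = "") -> None:
    _write_tsv(tic, path, header, index=False)


# ---------------------------------------------------------------------------
# sample metadata


def read_sample_meta(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata table and check controlled vocabularies."""
    meta = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in meta.columns:
        raise FormatError(f"{path}: metadata missing sample_id column")
    if meta["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id in metadata")
    for col, allowed in META_ENUMS.items():
        if col in meta.columns:
            bad = set(meta[col].dropna()) - set(allowed)
            if bad:
                raise FormatError(f"{path}: invalid {col} value(s): {sorted(bad)}")
    return meta.set_index("sample_id", drop=False)


def write_sample_meta(meta: pd.DataFrame, path: str | Path, header: str = "") -> None:
    _write_tsv(meta.reset_index(drop=True), path, header, index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[SignatureDefinition]:
    """Read an MSigDB-convention GMT file.

    Each line: set name, description, then gene symbols, tab-separated.
    Genes are uppercased and deduplicated.
    """
    sigs: list[SignatureDefinition] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            sigs.append(
                SignatureDefinition(name=fields[0], genes=tuple(fields[2:]), source=fields[1])
            )
    return sigs


def write_gmt(sigs: Iterable[SignatureDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sig in sigs:
            fh.write("\t".join([sig.name, sig.source, *sig.genes]) + "\n")


def packaged_signatures() -> dict[str, SignatureDefinition]:
    """Load the gene-set fixtures shipped with the package.

    Includes the 18-gene tumor inflammation signature (TIS), default
    AC/SCC histology marker panels, the MCM2-7 replicative helicase
    complex, a skin-keratin contaminant set, and small curated stand-ins
    (``*_SYNTHETIC``) for the published immune-cell-marker, actionable
    lung-cancer-marker and hallmark immune gene sets, which users should
    replace with the full published lists where licensing allows.
    """
    out: dict[str, SignatureDefinition] = {}
    data_dir = resources.files("slideproteo") / "data"
    for entry in sorted(data_dir.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".gmt"):
            with resources.as_file(entry) as p:
                for sig in read_gmt(p):
                    out[sig.name] = sig
    return out


# ---------------------------------------------------------------------------
# simulation ground truth (JSON)


def write_sim_truth(truth: "object", path: str | Path) -> None:
    """Serialize a :class:`~slideproteo.simulate.SimTruth` to JSON."""
    payload = {
        "samples": truth.samples.reset_index(drop=True).to_dict(orient="list"),
        "compartments": list(truth.compartments),
        "fractions": truth.fractions.round(12).to_dict(orient="split"),
        "immune_effect_log2": truth.immune_effect_log2,
        "curve_truth": list(truth.curve_truth),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_sim_truth_frames(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back the per-sample truth tables written by :func:`write_sim_truth`."""
    payload = json.loads(Path(path).read_text())
    samples = pd.DataFrame(payload["samples"]).set_index("sample_id", drop=False)
    fr = payload["fractions"]
    fractions = pd.DataFrame(fr["data"], index=fr["index"], columns=fr["columns"])
    return samples, fractions


# ---------------------------------------------------------------------------
# helpers


def _write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    header: str,
    index: bool,
    index_label: str | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        if header:
            for line in header.splitlines():
                fh.write(f"# {line}\n")
        frame.to_csv(fh, sep="\t", index=index, index_label=index_label, lineterminator="\n")
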