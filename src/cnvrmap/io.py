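"""Readers and writers for the delimited-text formats the pipeline touches.

Everything in memory is 1-based inclusive (:mod:`cnvrmap.model`); each
reader requires the file's coordinate convention to be declared through a
:class:`Dialect` and converts at the boundary.  BED files are 0-based
half-open by definition and use :data:`BED_DIALECT`.  The CNVR writer
emits the published table layout (``CNVR NO. / Chr / Start / End /
Length (Kb) / Status / Breed``) with ``Length (Kb) = (end - start)/1000``
-- the convention of the tables it must reproduce, distinct from the
inclusive length used internally.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Union

import pandas as pd

from cnvrmap.model import (
    CnvCall,
    Cnvr,
    FeatureRecord,
    GenomicInterval,
    QpcrAssay,
    SampleInfo,
    SnpRecord,
    normalize_chrom,
)
from cnvrmap.utils import format_kb

ONE_BASED_INCLUSIVE = "1-based-inclusive"
ZERO_BASED_HALF_OPEN = "0-based-half-open"
_COORD_SYSTEMS = (ONE_BASED_INCLUSIVE, ZERO_BASED_HALF_OPEN)


class FormatError(ValueError):
    """A malformed input row, reported with file, line and column."""

    def __init__(self, path, line_no, column, message):
        self.path = str(path)
        self.line_no = line_no
        self.column = column
        super().__init__(f"{path}:{line_no} column {column!r}: {message}")


#: Default state vocabulary.  Callers that emit copy-number integers map
#: 0/1 to loss and 3+ to gain; 2 is not a CNV state and is rejected.
DEFAULT_STATE_SYNONYMS: Dict[str, str] = {
    "gain": "gain",
    "loss": "loss",
    "duplication": "gain",
    "dup": "gain",
    "deletion": "loss",
    "del": "loss",
    "amplification": "gain",
    "0": "loss",
    "1": "loss",
    "3": "gain",
    "4": "gain",
    "5": "gain",
    "6": "gain",
}


@dataclass(frozen=True)
class Dialect:
    """Declares how a delimited file encodes intervals.

    ``coords`` must be stated explicitly -- there is no safe default for
    third-party caller output, so a missing declaration is refused
    rather than guessed.
    """

    coords: str
    delimiter: Optional[str] = None  # None = sniff among tab/comma
    state_synonyms: Dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_STATE_SYNONYMS)
    )

    def __post_init__(self) -> None:
        if self.coords not in _COORD_SYSTEMS:
            raise ValueError(
                "coordinate convention not declared: coords must be "
                f"one of {_COORD_SYSTEMS!r}, got {self.coords!r} "
                "(refusing to guess)"
            )


#: Convenience dialects.
TABLE_DIALECT = Dialect(coords=ONE_BASED_INCLUSIVE)
BED_DIALECT = Dialect(coords=ZERO_BASED_HALF_OPEN, delimiter="\t")


def _to_internal(start: int, end: int, coords: str) -> tuple:
    if coords == ZERO_BASED_HALF_OPEN:
        return start + 1, end
    return start, end


def _sniff_delimiter(path: Path, declared: Optional[str]) -> str:
    if declared is not None:
        return declared
    with open(path, newline="") as fh:
        sample = fh.read(8192)
    try:
        return csv.Sniffer().sniff(sample, delimiters="\t,").delimiter
    except csv.Error:
        return "\t"


def _open_reader(path, dialect: Dialect):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    delim = _sniff_delimiter(path, dialect.delimiter)
    fh = open(path, newline="")
    return fh, csv.reader(fh, delimiter=delim)


def _parse_int(value, path, line_no, column):
    try:
        return int(value)
    except (TypeError, ValueError):
        raise FormatError(path, line_no, column, f"not an integer: {value!r}")


# ---------------------------------------------------------------------------
# CNV calls
# ---------------------------------------------------------------------------

CALL_COLUMNS = ["sample", "chrom", "start", "end", "state", "n_snps"]


def read_cnv_calls(
    path, algorithm_id: str, dialect: Dialect
) -> List[CnvCall]:
    """Read one algorithm's call table into validated :class:`CnvCall` rows.

    The file needs a header resolving the columns ``sample, chrom,
    start, end, state, n_snps`` (case-insensitive); row order is
    preserved.  State tokens go through ``dialect.state_synonyms`` so
    copy-number integers and duplication/deletion vocabulary normalize
    to gain/loss.
    """
    fh, reader = _open_reader(path, dialect)
    calls: List[CnvCall] = []
    with fh:
        header = next(reader, None)
        if header is None:
            raise FormatError(path, 1, "header", "empty file")
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        missing = [c for c in CALL_COLUMNS if c not in cols]
        if missing:
            raise FormatError(
                path, 1, ",".join(missing), f"missing required columns {missing}"
            )
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            if len(row) < len(header):
                raise FormatError(
                    path, line_no, "*", f"expected {len(header)} fields, got {len(row)}"
                )
            raw_start = _parse_int(row[cols["start"]], path, line_no, "start")
            raw_end = _parse_int(row[cols["end"]], path, line_no, "end")
            start, end = _to_internal(raw_start, raw_end, dialect.coords)
            token = row[cols["state"]].strip().lower()
            state = dialect.state_synonyms.get(token)
            if state is None:
                raise FormatError(
                    path,
                    line_no,
                    "state",
                    f"unknown state token {token!r}; accepted: "
                    f"{sorted(set(dialect.state_synonyms))}",
                )
            n_snps = _parse_int(row[cols["n_snps"]], path, line_no, "n_snps")
            try:
                interval = GenomicInterval(row[cols["chrom"]], start, end)
                call = CnvCall(
                    sample_id=row[cols["sample"]].strip(),
                    algorithm_id=algorithm_id,
                    interval=interval,
                    state=state,
                    n_snps=n_snps,
                )
            except ValueError as exc:
                raise FormatError(path, line_no, "*", str(exc)) from exc
            calls.append(call)
    return calls


def write_cnv_calls(calls: Sequence[CnvCall], path) -> None:
    """Write calls as 1-based inclusive TSV (round-trips with the reader)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CALL_COLUMNS)
        for c in calls:
            writer.writerow(
                [
                    c.sample_id,
                    c.interval.chrom,
                    c.interval.start,
                    c.interval.end,
                    c.state,
                    c.n_snps,
                ]
            )


# ---------------------------------------------------------------------------
# Features (delimited tables, BED, minimal GFF3)
# ---------------------------------------------------------------------------

FEATURE_COLUMNS = ["feature_id", "chrom", "start", "end"]


def read_features(path, kind: str, dialect: Dialect) -> List[FeatureRecord]:
    """Read an annotation file into :class:`FeatureRecord` objects.

    Dispatches on extension: ``.bed`` (headerless, always 0-based
    half-open regardless of the dialect's declaration), ``.gff3``/
    ``.gff`` (1-based inclusive, ``key=value`` attributes only), and
    otherwise a headered delimited table with columns ``feature_id,
    chrom, start, end`` plus any extra columns as attributes.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".bed":
        return _read_bed(path, kind)
    if suffix in (".gff", ".gff3"):
        return _read_gff3(path, kind)
    return _read_feature_table(path, kind, dialect)


def _read_bed(path: Path, kind: str) -> List[FeatureRecord]:
    features: List[FeatureRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(path, line_no, "*", "BED needs >= 3 fields")
            start0 = _parse_int(parts[1], path, line_no, "start")
            end0 = _parse_int(parts[2], path, line_no, "end")
            start, end = _to_internal(start0, end0, ZERO_BASED_HALF_OPEN)
            name = parts[3] if len(parts) > 3 else f"{kind}_{line_no}"
            attrs = {}
            if len(parts) > 4:
                attrs["score"] = parts[4]
            try:
                features.append(
                    FeatureRecord(
                        feature_id=name,
                        interval=GenomicInterval(parts[0], start, end),
                        kind=kind,
                        attributes=attrs,
                    )
                )
            except ValueError as exc:
                raise FormatError(path, line_no, "*", str(exc)) from exc
    return features


def _read_gff3(path: Path, kind: str) -> List[FeatureRecord]:
    features: List[FeatureRecord] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 9:
                raise FormatError(path, line_no, "*", "GFF3 needs 9 fields")
            start = _parse_int(parts[3], path, line_no, "start")
            end = _parse_int(parts[4], path, line_no, "end")
            attrs: Dict[str, str] = {}
            for pair in parts[8].split(";"):
                pair = pair.strip()
                if pair and "=" in pair:
                    key, _, value = pair.partition("=")
                    attrs[key.strip()] = value.strip()
            fid = attrs.get("ID") or attrs.get("Name") or f"{kind}_{line_no}"
            try:
                features.append(
                    FeatureRecord(
                        feature_id=fid,
                        interval=GenomicInterval(parts[0], start, end),
                        kind=kind,
                        attributes=attrs,
                    )
                )
            except ValueError as exc:
                raise FormatError(path, line_no, "*", str(exc)) from exc
    return features


def _read_feature_table(path: Path, kind: str, dialect: Dialect) -> List[FeatureRecord]:
    fh, reader = _open_reader(path, dialect)
    features: List[FeatureRecord] = []
    with fh:
        header = next(reader, None)
        if header is None:
            raise FormatError(path, 1, "header", "empty file")
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        missing = [c for c in FEATURE_COLUMNS if c not in cols]
        if missing:
            raise FormatError(
                path, 1, ",".join(missing), f"missing required columns {missing}"
            )
        extra = [
            (name.strip(), i)
            for i, name in enumerate(header)
            if name.strip().lower() not in FEATURE_COLUMNS
        ]
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            raw_start = _parse_int(row[cols["start"]], path, line_no, "start")
            raw_end = _parse_int(row[cols["end"]], path, line_no, "end")
            start, end = _to_internal(raw_start, raw_end, dialect.coords)
            attrs = {
                name: row[i] for name, i in extra if i < len(row) and row[i] != ""
            }
            try:
                features.append(
                    FeatureRecord(
                        feature_id=row[cols["feature_id"]].strip(),
                        interval=GenomicInterval(row[cols["chrom"]], start, end),
                        kind=kind,
                        attributes=attrs,
                    )
                )
            except ValueError as exc:
                raise FormatError(path, line_no, "*", str(exc)) from exc
    return features


def write_features(features: Sequence[FeatureRecord], path) -> None:
    """Write features as a 1-based inclusive TSV table."""
    attr_keys: List[str] = []
    for f in features:
        for k in f.attributes:
            if k not in attr_keys:
                attr_keys.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(FEATURE_COLUMNS + attr_keys)
        for f in features:
            writer.writerow(
                [f.feature_id, f.interval.chrom, f.interval.start, f.interval.end]
                + [f.attributes.get(k, "") for k in attr_keys]
            )


# ---------------------------------------------------------------------------
# CNVR tables
# ---------------------------------------------------------------------------

CNVR_HEADER = ["CNVR NO.", "Chr", "Start", "End", "Length (Kb)", "Status", "Breed"]
_STATUS_OUT = {"gain": "Gain", "loss": "Loss", "gain-loss": "Gain-Loss"}
_STATUS_IN = {
    "gain": "gain",
    "loss": "loss",
    "gain-loss": "gain-loss",
    "gainloss": "gain-loss",
    "gain/loss": "gain-loss",
    "both": "gain-loss",
}


def write_cnvrs(
    cnvrs: Sequence[Cnvr],
    path,
    breeds: Optional[Dict[int, str]] = None,
) -> None:
    """Write CNVRs in the published table layout.

    ``Length (Kb)`` is ``(end - start) / 1000`` -- deliberately the span
    convention, not the inclusive length.  An empty list produces a
    header-only file.
    """
    breeds = breeds or {}
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(CNVR_HEADER)
        for r in cnvrs:
            writer.writerow(
                [
                    r.cnvr_id,
                    r.interval.chrom,
                    r.interval.start,
                    r.interval.end,
                    format_kb(r.interval.span_bp),
                    _STATUS_OUT[r.status],
                    breeds.get(r.cnvr_id, ""),
                ]
            )


def read_cnvrs(path) -> List[Cnvr]:
    """Read a CNVR table written by :func:`write_cnvrs` (or hand-made)."""
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise FormatError(path, 1, "header", "empty file")
        cols = {name.strip().lower(): i for i, name in enumerate(header)}
        idx_id = cols.get("cnvr no.", cols.get("cnvr_id"))
        idx_chr = cols.get("chr", cols.get("chrom"))
        idx_status = cols.get("status")
        if idx_id is None or idx_chr is None or idx_status is None:
            raise FormatError(path, 1, "*", f"unrecognized CNVR header {header}")
        cnvrs: List[Cnvr] = []
        for line_no, row in enumerate(reader, start=2):
            if not row or all(not cell.strip() for cell in row):
                continue
            token = row[idx_status].strip().lower().replace(" ", "")
            status = _STATUS_IN.get(token)
            if status is None:
                raise FormatError(
                    path, line_no, "Status",
                    f"unknown status {row[idx_status]!r}",
                )
            try:
                cnvrs.append(
                    Cnvr(
                        cnvr_id=_parse_int(row[idx_id], path, line_no, "CNVR NO."),
                        interval=GenomicInterval(
                            row[idx_chr],
                            _parse_int(row[cols["start"]], path, line_no, "Start"),
                            _parse_int(row[cols["end"]], path, line_no, "End"),
                        ),
                        status=status,
                    )
                )
            except ValueError as exc:
                raise FormatError(path, line_no, "*", str(exc)) from exc
    return cnvrs


def read_cnvr_breeds(path) -> Dict[int, str]:
    """Return the Breed column of a CNVR table keyed by CNVR number."""
    df = pd.read_csv(path, sep="\t")
    id_col = "CNVR NO." if "CNVR NO." in df.columns else "cnvr_id"
    if "Breed" not in df.columns:
        return {}
    return dict(zip(df[id_col].astype(int), df["Breed"].astype(str)))


# ---------------------------------------------------------------------------
# Genotypes, SNP map, samples
# ---------------------------------------------------------------------------


def read_genotypes(path) -> pd.DataFrame:
    """Read a sample x SNP genotype matrix (TSV, first column sample_id).

    Cells are AA/AB/BB or ``--`` for missing (``NC``, ``NN`` and empty
    cells normalize to ``--``).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df = df.fillna("--").replace({"NC": "--", "NN": "--", "": "--"})
    bad = set(df.values.ravel()) - {"AA", "AB", "BB", "--"}
    if bad:
        raise FormatError(path, 0, "*", f"invalid genotype tokens {sorted(bad)}")
    return df


def write_genotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample_id")


def read_snp_map(path) -> List[SnpRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    return [
        SnpRecord(row.snp_id, row.chrom, int(row.pos))
        for row in df.itertuples(index=False)
    ]


def write_snp_map(snps: Iterable[SnpRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["snp_id", "chrom", "pos"])
        for s in snps:
            writer.writerow([s.snp_id, s.chrom, s.pos])


def read_samples(path) -> List[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        SampleInfo(row.sample_id, row.generation, row.breed, getattr(row, "sex", ""))
        for row in df.itertuples(index=False)
    ]


def write_samples(samples: Iterable[SampleInfo], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample_id", "generation", "breed", "sex"])
        for s in samples:
            writer.writerow([s.sample_id, s.generation, s.breed, s.sex])


# ---------------------------------------------------------------------------
# qPCR assays
# ---------------------------------------------------------------------------


def read_qpcr_assays(path) -> List[QpcrAssay]:
    """Read a long-format CT table into per-sample assays.

    Columns: ``cnvr_id, sample_id, role, target_cts, control_cts`` where
    ``role`` is ``test`` or ``calibrator`` (exactly one calibrator per
    CNVR) and the CT columns hold comma-separated replicate values.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cnvr_id", "sample_id", "role", "target_cts", "control_cts"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(path, 1, ",".join(sorted(missing)), "missing columns")
    assays: List[QpcrAssay] = []
    for cnvr_id, group in df.groupby("cnvr_id", sort=False):
        cal = group[group["role"] == "calibrator"]
        if len(cal) != 1:
            raise FormatError(
                path, 0, "role",
                f"cnvr {cnvr_id!r} needs exactly one calibrator row, "
                f"found {len(cal)}",
            )
        cal_t = _split_cts(cal.iloc[0]["target_cts"])
        cal_c = _split_cts(cal.iloc[0]["control_cts"])
        for row in group[group["role"] == "test"].itertuples(index=False):
            assays.append(
                QpcrAssay(
                    sample_id=row.sample_id,
                    cnvr_id=str(cnvr_id),
                    target_ct=_split_cts(row.target_cts),
                    control_ct=_split_cts(row.control_cts),
                    calibrator_target_ct=cal_t,
                    calibrator_control_ct=cal_c,
                )
            )
    return assays


def _split_cts(cell: str) -> tuple:
    return tuple(float(v) for v in str(cell).split(",") if v.strip())


def write_qpcr_assays(rows: Sequence[dict], path) -> None:
    """Write long-format CT rows (dicts with the reader's columns)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["cnvr_id", "sample_id", "role", "target_cts", "control_cts"])
        for r in rows:
            writer.writerow(
                [r["cnvr_id"], r["sample_id"], r["role"], r["target_cts"], r["control_cts"]]
            )
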