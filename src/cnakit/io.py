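"""Readers and writers for every format the pipeline touches.

Probe tables are tab-delimited with header ``ProbeID Chrom Start End
Log2Ratio``; cohort CNA tables carry one classified call per row; genomic
regions exchange as BED (0-based half-open, converted on read); cytobands
as UCSC ``cytoBand.txt``; the genome model as ``chrom.sizes``.  The packaged
fixtures (cohort CNA tables, MCR catalog, germline-CNV regions, IG loci,
genome, cytobands) are content-hashed and verified on load.

``parse_cna_notation`` reads the tables' ISCN-like dialect
(``−7q33q34<135.74–137.48>[0.16]``), tolerating ASCII hyphens and decimal
commas; the writer counterpart is :func:`cnakit.karyotype.format_cna`.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml

from .classify import (
    ClassificationThresholds,
    CNACall,
    CNVFilterParams,
    NamedLocus,
)
from .intervals import GenomeModel, GenomicInterval
from .karyotype import CytobandMap
from .mcr import MCR, _chrom_key
from .segmentation import DetectionParams, ProbeMeasurement, ProbeProfile, Segment
from .stats import PatientProfile

__all__ = [
    "read_probe_table",
    "write_probe_table",
    "read_cna_table",
    "write_cna_table",
    "write_segments_bed",
    "write_mcr_table",
    "parse_cna_notation",
    "ParsedCNA",
    "load_fixture",
    "load_genome",
    "load_cytobands",
    "default_cnv_filter_params",
    "RunConfig",
]

_DATA = resources.files("cnakit") / "data"

# sha256 of the packaged fixtures (verified on load)
_CHECKSUMS: dict[str, str] = {}  # populated at module end


class FormatError(ValueError):
    """Malformed input file or token."""


# ---------------------------------------------------------------------------
# probe tables
# ---------------------------------------------------------------------------

_PROBE_COLUMNS = ["ProbeID", "Chrom", "Start", "End", "Log2Ratio"]


def read_probe_table(path, sample_id: str | None = None, role: str = "combined") -> ProbeProfile:
    """Read a tab-delimited probe table into a sorted, validated profile."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _PROBE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    probes = []
    for row in df.itertuples():
        line = row.Index + 2  # header on line 1
        try:
            start, end = int(row.Start), int(row.End)
            ratio = float(row.Log2Ratio)
        except (TypeError, ValueError):
            raise FormatError(
                f"{path}:{line}: non-numeric coordinate or ratio "
                f"({row.Start!r}, {row.End!r}, {row.Log2Ratio!r})"
            ) from None
        if ratio != ratio:  # NaN
            raise FormatError(f"{path}:{line}: missing log2 ratio")
        probes.append(
            ProbeMeasurement(str(row.ProbeID), GenomicInterval(str(row.Chrom), start, end), ratio)
        )
    probes.sort(key=lambda p: (_chrom_key(p.interval.chrom), p.interval.start))
    return ProbeProfile(sample_id or path.stem, tuple(probes), role=role)


def write_probe_table(profile: ProbeProfile, path) -> None:
    df = pd.DataFrame(
        {
            "ProbeID": [p.probe_id for p in profile.probes],
            "Chrom": [p.interval.chrom for p in profile.probes],
            "Start": [p.interval.start for p in profile.probes],
            "End": [p.interval.end for p in profile.probes],
            "Log2Ratio": [repr(p.log2_ratio) for p in profile.probes],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# cohort CNA tables
# ---------------------------------------------------------------------------

_CNA_COLUMNS = [
    "patient",
    "group",
    "direction",
    "chrom",
    "band_span",
    "start_mb",
    "end_mb",
    "linear_ratio",
    "ig",
]


def _calls_from_frame(df: pd.DataFrame) -> list[CNACall]:
    calls = []
    for row in df.to_dict("records"):
        call = CNACall.from_ratio(
            patient=str(row["patient"]),
            interval=GenomicInterval.from_mb(
                str(row["chrom"]), float(row["start_mb"]), float(row["end_mb"])
            ),
            linear_ratio=float(row["linear_ratio"]),
            direction=str(row["direction"]),
            band_span=str(row.get("band_span", "") or ""),
        )
        if int(row.get("ig", 0)):
            call = call.with_flag("IG", "transcribed_asterisk")
        if int(row.get("cnv", 0)):
            call = call.with_flag("CNV", "transcribed_cnv")
        calls.append(call)
    return calls


def read_cna_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False, na_values=[])
    missing = [c for c in _CNA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_cna_table(calls: Sequence[CNACall], groups: dict, path) -> None:
    rows = []
    for c in calls:
        rows.append(
            {
                "patient": c.patient,
                "group": groups.get(c.patient, ""),
                "direction": c.direction,
                "chrom": c.interval.chrom,
                "band_span": c.band_span or "",
                "start_mb": f"{c.interval.start_mb:.2f}",
                "end_mb": f"{c.interval.end_mb:.2f}",
                "linear_ratio": f"{c.linear_ratio:.2f}",
                "ig": int("IG" in c.flags),
                "cnv": int("CNV" in c.flags),
                "state": c.state.value,
                "reasons": ";".join(c.reasons),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_segments_bed(segments: Sequence[Segment], path) -> None:
    """BED with name field ``state|ratio|nprobes`` (0-based half-open)."""
    with open(path, "w") as fh:
        for seg in segments:
            chrom, start, end = seg.interval.to_bed()
            state = "gain" if seg.mean_log2 > 0 else "loss"
            fh.write(
                f"{chrom}\t{start}\t{end}\t{state}|{seg.linear_ratio:.3f}|{seg.n_probes}\n"
            )


def write_mcr_table(mcrs: Sequence[MCR], path) -> None:
    rows = [
        {
            "chrom": m.interval.chrom,
            "start_mb": f"{m.interval.start_mb:.2f}",
            "end_mb": f"{m.interval.end_mb:.2f}",
            "direction": m.direction,
            "size_mb": f"{m.size_mb:.2f}",
            "n_support": len(m.support),
            "patients": ",".join(sorted(m.support)),
            "amplified": int(m.amplified),
        }
        for m in mcrs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# CNA token notation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParsedCNA:
    direction: str
    chrom: str
    band_span: str
    interval: GenomicInterval
    linear_ratio: float | None


_TOKEN_RE = re.compile(
    r"""^\s*
    (?P<sign>[+\-−])\s*
    (?P<chrom>\d{1,2}|X|Y)\s*
    (?P<band>[pq][pqter0-9.]*)?\s*
    <\s*(?P<start>[\d.,]+)\s*[–−=\-]\s*(?P<end>[\d.,]+)\s*>
    \s*(?:\[\s*(?P<ratio>[\d.,]+)\s*\])?\s*\.?\s*$
    """,
    re.VERBOSE,
)


def _num(text: str) -> float:
    # the tables use decimal commas in places ("27,15")
    return float(text.replace(",", "."))


def parse_cna_notation(token: str) -> ParsedCNA:
    """Parse one table token, e.g. ``−7q33q34<135.74–137.48>[0.16]``."""
    m = _TOKEN_RE.match(token)
    if not m:
        raise FormatError(f"unparseable CNA token: {token!r}")
    start, end = _num(m.group("start")), _num(m.group("end"))
    if start >= end:
        raise FormatError(f"CNA token has start >= end: {token!r}")
    return ParsedCNA(
        direction="gain" if m.group("sign") == "+" else "loss",
        chrom=m.group("chrom"),
        band_span=m.group("band") or "",
        interval=GenomicInterval.from_mb(m.group("chrom"), start, end),
        linear_ratio=_num(m.group("ratio")) if m.group("ratio") else None,
    )


# ---------------------------------------------------------------------------
# packaged fixtures
# ---------------------------------------------------------------------------

_FIXTURE_FILES = {
    "table4": "taml_cna_table.tsv",
    "table5": "paml_cna_table.tsv",
    "table6": "mcr_catalog.tsv",
    "patients": "patients.tsv",
    "cytobands": "cytobands_synthetic.txt",
    "genome": "hg18.chrom.sizes",
    "cnv_db": "germline_cnv_regions.bed",
    "ig_loci": "ig_loci.tsv",
    "cnv_gene_loci": "cnv_gene_loci.tsv",
}


def _fixture_bytes(name: str) -> bytes:
    try:
        filename = _FIXTURE_FILES[name]
    except KeyError:
        raise FormatError(f"unknown fixture {name!r}") from None
    data = (_DATA / filename).read_bytes()
    expected = _CHECKSUMS.get(filename)
    if expected is not None:
        digest = hashlib.sha256(data).hexdigest()
        if digest != expected:
            raise FormatError(
                f"fixture {filename} checksum mismatch: {digest} != {expected}"
            )
    return data


def _fixture_frame(name: str) -> pd.DataFrame:
    import io as _io

    return pd.read_csv(
        _io.BytesIO(_fixture_bytes(name)),
        sep="\t",
        comment="#",
        keep_default_na=False,
        na_values=[],
    )


def load_genome(path=None) -> GenomeModel:
    """Genome model from a chrom.sizes file (default: packaged hg18)."""
    if path is None:
        text = _fixture_bytes("genome").decode()
    else:
        text = Path(path).read_text()
    pairs = []
    for line_no, line in enumerate(text.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise FormatError(f"chrom.sizes line {line_no}: expected 2 columns")
        pairs.append((parts[0], int(parts[1])))
    return GenomeModel.from_pairs(pairs)


def load_cytobands(path=None) -> CytobandMap:
    """Cytoband map from a UCSC cytoBand.txt (0-based half-open on disk)."""
    if path is None:
        text = _fixture_bytes("cytobands").decode()
    else:
        text = Path(path).read_text()
    bands: dict[str, list[tuple[int, int, str]]] = {}
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        chrom, start, end, name = line.split("\t")[:4]
        bands.setdefault(chrom, []).append((int(start) + 1, int(end), name))
    return CytobandMap({c: tuple(v) for c, v in bands.items()})


def load_cnv_db(path=None) -> list[GenomicInterval]:
    """Known-CNV regions from BED (0-based half-open on disk)."""
    if path is None:
        text = _fixture_bytes("cnv_db").decode()
    else:
        text = Path(path).read_text()
    out = []
    for line in text.splitlines():
        if not line.strip() or line.startswith(("#", "track")):
            continue
        chrom, start, end = line.split("\t")[:3]
        out.append(GenomicInterval(chrom, int(start) + 1, int(end)))
    return out


def _load_loci(name: str) -> tuple[NamedLocus, ...]:
    df = _fixture_frame(name)
    return tuple(
        NamedLocus(
            str(row["name"]),
            GenomicInterval.from_mb(
                str(row["chrom"]), float(row["start_mb"]), float(row["end_mb"])
            ),
        )
        for row in df.to_dict("records")
    )


def default_cnv_filter_params(**overrides) -> CNVFilterParams:
    """CNV/IG filter parameters with the packaged locus tables."""
    kw = dict(
        cnv_gene_loci=_load_loci("cnv_gene_loci"),
        ig_loci=_load_loci("ig_loci"),
    )
    kw.update(overrides)
    return CNVFilterParams(**kw)


def _cohort_profiles(table_name: str) -> list[PatientProfile]:
    calls_df = _fixture_frame(table_name)
    patients_df = _fixture_frame("patients")
    group = "t-AML" if table_name == "table4" else "p-AML"
    calls = _calls_from_frame(calls_df)
    by_patient: dict[str, list[CNACall]] = {}
    for c in calls:
        by_patient.setdefault(c.patient, []).append(c)
    out = []
    for row in patients_df.itertuples():
        if row.group != group:
            continue
        out.append(
            PatientProfile(
                patient=str(row.patient),
                group=group,
                calls=tuple(by_patient.get(str(row.patient), ())),
                karyotype=str(row.prefix),
            )
        )
    return out


def _mcr_catalog() -> dict[str, list[MCR]]:
    df = _fixture_frame("table6")
    catalog: dict[str, list[MCR]] = {"t-AML": [], "p-AML": []}
    for row in df.itertuples():
        patients = tuple(p.strip() for p in str(row.patients).split(","))
        catalog[str(row.group)].append(
            MCR(
                interval=GenomicInterval.from_mb(
                    str(row.chrom), float(row.start_mb), float(row.end_mb)
                ),
                direction=str(row.direction),
                support=frozenset(patients),
                seed_patient=patients[0],
                amplified=bool(int(row.amp)),
            )
        )
    return catalog


def load_fixture(name: str):
    """Load a packaged fixture by logical name.

    ``table4``/``table5``: cohort patient profiles (30 t-AML / 36 p-AML);
    ``table6``: published MCR catalog split by group; ``cytobands``/
    ``genome``/``cnv_db``/``ig_loci``/``cnv_gene_loci``: supporting maps.
    Fixture files are checksummed; a mismatch raises.
    """
    if name in ("table4", "table5"):
        return _cohort_profiles(name)
    if name == "table6":
        return _mcr_catalog()
    if name == "cytobands":
        return load_cytobands()
    if name == "genome":
        return load_genome()
    if name == "cnv_db":
        return load_cnv_db()
    if name in ("ig_loci", "cnv_gene_loci"):
        return _load_loci(name)
    if name == "patients":
        return _fixture_frame("patients")
    raise FormatError(f"unknown fixture {name!r}")


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    detection: DetectionParams = field(default_factory=DetectionParams)
    thresholds: ClassificationThresholds = field(default_factory=ClassificationThresholds)
    cnv: CNVFilterParams | None = None
    mcr_min_support: int = 2
    report_gap_tol_mb: float = 2.0
    report_ratio_tol_log2: float = 0.2
    seed: int = 0
    log_level: str = "INFO"

    _BLOCKS = {
        "detection": DetectionParams,
        "thresholds": ClassificationThresholds,
        "cnv": CNVFilterParams,
    }
    _SCALARS = {"mcr_min_support", "report_gap_tol_mb", "report_ratio_tol_log2", "seed", "log_level"}

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls._BLOCKS) - cls._SCALARS
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        kw = {}
        for block, target in cls._BLOCKS.items():
            if block in raw:
                try:
                    kw[block] = target(**raw[block])
                except TypeError as exc:
                    raise FormatError(f"config block {block!r}: {exc}") from None
        for key in cls._SCALARS:
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)


# sha256 digests of the packaged data files; regenerated when fixtures change
from ._checksums import CHECKSUMS as _CHECKSUMS  # noqa: E402
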