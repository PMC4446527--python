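"""Readers and writers for the pipeline's file formats.

Conventions: bedGraph and BED are written 0-based half-open, as the format
standards require.  TSV tables and human-readable reports use 1-based
inclusive positions, the convention genome browsers print.  All writers'
output re-parses under the corresponding reader (round-trip safe), and
malformed lines are reported with their line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .peakcall import Peak, ProbeTrack
from .simulate import FibreObservation, GroundTruth, QpcrExperiment
from .snp_phase import HomologDomain, MarkerKind, MarkerObservation

__all__ = [
    "read_bedgraph",
    "write_bedgraph",
    "write_bed",
    "read_bed",
    "read_bed_domains",
    "write_peaks_bed",
    "read_marker_tsv",
    "write_marker_tsv",
    "read_qpcr_tsv",
    "write_qpcr_tsv",
    "read_fibre_tsv",
    "write_fibre_tsv",
    "write_ground_truth_json",
    "read_ground_truth_json",
]


class ParseError(ValueError):
    """A malformed input line, reported with file and line number."""


def _fail(path, lineno: int, msg: str) -> None:
    raise ParseError(f"{path}:{lineno}: {msg}")


# ---------------------------------------------------------------- bedGraph

def read_bedgraph(
    path: str | Path, individual_id: str = "sample", allow_unsorted: bool = False
) -> ProbeTrack:
    """Read a probe track from bedGraph (chrom, start, end, log2 ratio).

    The probe position is taken as the interval start.  Tracks must be
    sorted by position unless ``allow_unsorted`` (then they are sorted).
    """
    chroms: list[str] = []
    positions: list[int] = []
    ratios: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, f"expected 4 columns, got {len(fields)}")
            try:
                start, end, value = int(fields[1]), int(fields[2]), float(fields[3])
            except ValueError:
                _fail(path, lineno, f"non-numeric coordinates or value: {line!r}")
            if start >= end:
                _fail(path, lineno, f"start {start} >= end {end}")
            chroms.append(fields[0])
            positions.append(start)
            ratios.append(value)
    if not positions:
        raise ParseError(f"{path}: no probe records")
    if len(set(chroms)) > 1:
        raise ParseError(f"{path}: multiple chromosomes in one track")
    pos = np.asarray(positions)
    rat = np.asarray(ratios)
    if np.any(np.diff(pos) <= 0):
        if not allow_unsorted:
            raise ParseError(f"{path}: probe positions not strictly increasing")
        order = np.argsort(pos, kind="stable")
        pos, rat = pos[order], rat[order]
    return ProbeTrack(chroms[0], pos, rat, individual_id)


def write_bedgraph(track: ProbeTrack, path: str | Path, span: int | None = None) -> None:
    """Write a probe track as bedGraph; each probe covers [pos, pos+span)."""
    if span is None:
        span = int(track.median_spacing) or 1
    with open(path, "w") as fh:
        for pos, ratio in zip(track.positions.tolist(), track.ratios.tolist()):
            fh.write(f"{track.chrom}\t{pos}\t{pos + span}\t{ratio:.6g}\n")


# --------------------------------------------------------------------- BED

def write_bed(
    intervals: list[tuple[str, int, int, str, float, str]], path: str | Path
) -> None:
    """Write BED6 records (chrom, start, end, name, score, strand)."""
    with open(path, "w") as fh:
        for chrom, start, end, name, score, strand in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\t{score:g}\t{strand}\n")


def write_peaks_bed(peaks: list[Peak], path: str | Path) -> None:
    """BED6 peaks; score = mean log2 ratio scaled x100, capped at 1000."""
    write_bed(
        [
            (
                p.chrom,
                p.start,
                p.end,
                f"peak{i + 1}",
                min(1000.0, round(100 * p.mean_ratio)),
                ".",
            )
            for i, p in enumerate(peaks)
        ],
        path,
    )


def write_domains_bed(domains: list[HomologDomain], path: str | Path) -> None:
    """BED6 phased domains; name = individualId_homolog."""
    write_bed(
        [
            (d.chrom, d.start, d.end, f"{d.individual_id}_{d.homolog}", 0.0, ".")
            for d in domains
        ],
        path,
    )


def read_bed(path: str | Path) -> list[tuple[str, int, int, str, float, str]]:
    """Read BED records back as (chrom, start, end, name, score, strand)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                _fail(path, lineno, "BED records need at least 3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                _fail(path, lineno, f"non-integer coordinates: {line!r}")
            if start >= end:
                _fail(path, lineno, f"start {start} >= end {end}")
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 else 0.0
            strand = fields[5] if len(fields) > 5 else "."
            records.append((fields[0], start, end, name, score, strand))
    return records


def read_bed_domains(path: str | Path) -> list[HomologDomain]:
    """Read phased domains back from BED6 (name = individualId_homolog)."""
    domains = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                _fail(path, lineno, "BED domain records need at least 4 columns")
            name = fields[3]
            if "_" not in name:
                _fail(path, lineno, f"domain name {name!r} lacks _homolog suffix")
            ind, homolog = name.rsplit("_", 1)
            try:
                domains.append(
                    HomologDomain(ind, int(homolog), fields[0], int(fields[1]), int(fields[2]))
                )
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return domains


# ------------------------------------------------------------- marker TSV

_MARKER_COLUMNS = [
    "chrom", "pos", "allele_a", "allele_b",
    "input_a", "input_b", "ip_a", "ip_b", "marker_kind", "marker_id",
]


def write_marker_tsv(markers: list[MarkerObservation], path: str | Path) -> None:
    """Marker table; ``pos`` is written 1-based."""
    with open(path, "w") as fh:
        fh.write("\t".join(_MARKER_COLUMNS) + "\n")
        for m in markers:
            fh.write(
                f"{m.chrom}\t{m.pos + 1}\t{m.allele_a}\t{m.allele_b}\t"
                f"{m.input_a}\t{m.input_b}\t{m.ip_a}\t{m.ip_b}\t"
                f"{m.marker_kind.value}\t{m.marker_id}\n"
            )


def read_marker_tsv(path: str | Path) -> list[MarkerObservation]:
    markers = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:8] != _MARKER_COLUMNS[:8]:
            raise ParseError(f"{path}:1: unexpected marker header {header!r}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 8:
                _fail(path, lineno, f"expected >=8 columns, got {len(f)}")
            try:
                markers.append(
                    MarkerObservation(
                        chrom=f[0],
                        pos=int(f[1]) - 1,
                        allele_a=f[2],
                        allele_b=f[3],
                        input_a=int(f[4]),
                        input_b=int(f[5]),
                        ip_a=int(f[6]),
                        ip_b=int(f[7]),
                        marker_kind=MarkerKind(f[8]) if len(f) > 8 else MarkerKind.SNP,
                        marker_id=f[9] if len(f) > 9 else "",
                    )
                )
            except ValueError as exc:
                _fail(path, lineno, str(exc))
    return markers


# --------------------------------------------------------------- qPCR TSV

def write_qpcr_tsv(exp: QpcrExperiment, path: str | Path) -> None:
    """Measurements table (1-based amplicon coordinates) plus standard
    curves as ``dilution`` rows; the control amplicon is flagged."""
    control = tuple(exp.control_amplicon)
    with open(path, "w") as fh:
        fh.write("amplicon_start\tamplicon_end\trecord\tsample\treplicate\tvalue\tis_control\n")
        for amp, sample, rep, ct in exp.measurements:
            flag = int(tuple(amp) == control)
            fh.write(f"{amp[0] + 1}\t{amp[1]}\tCt\t{sample}\t{rep}\t{ct:.6g}\t{flag}\n")
        for amp, points in exp.standard_curves.items():
            flag = int(tuple(amp) == control)
            for k, (dil, ct) in enumerate(points):
                fh.write(
                    f"{amp[0] + 1}\t{amp[1]}\tdilution:{dil:g}\tinput\t{k}\t{ct:.6g}\t{flag}\n"
                )


def read_qpcr_tsv(path: str | Path) -> QpcrExperiment:
    measurements = []
    curves: dict[tuple[int, int], list[tuple[float, float]]] = {}
    control: tuple[int, int] | None = None
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("amplicon_start"):
            raise ParseError(f"{path}:1: unexpected qPCR header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 7:
                _fail(path, lineno, f"expected 7 columns, got {len(f)}")
            try:
                amp = (int(f[0]) - 1, int(f[1]))
                value = float(f[5])
            except ValueError:
                _fail(path, lineno, f"non-numeric fields: {line!r}")
            if int(f[6]):
                control = amp
            if f[2] == "Ct":
                measurements.append((amp, f[3], int(f[4]), value))
            elif f[2].startswith("dilution:"):
                curves.setdefault(amp, []).append((float(f[2].split(":", 1)[1]), value))
            else:
                _fail(path, lineno, f"unknown record type {f[2]!r}")
    if control is None:
        raise ParseError(f"{path}: no control amplicon flagged")
    return QpcrExperiment(measurements, control, curves)


# -------------------------------------------------------------- fibre TSV

def write_fibre_tsv(fibres: list[FibreObservation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("fibre_id\tcrest_start\tcrest_end\tbac_start\tbac_end\ttrue_homolog\tpattern\n")
        for f in fibres:
            for s, e in f.crest_intervals:
                fh.write(
                    f"{f.fibre_id}\t{s:.2f}\t{e:.2f}\t{f.bac_interval[0]:.2f}\t"
                    f"{f.bac_interval[1]:.2f}\t{f.true_homolog}\t{f.pattern}\n"
                )


def read_fibre_tsv(path: str | Path) -> list[FibreObservation]:
    by_id: dict[str, FibreObservation] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("fibre_id"):
            raise ParseError(f"{path}:1: unexpected fibre header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 7:
                _fail(path, lineno, f"expected 7 columns, got {len(f)}")
            fid = f[0]
            crest = (float(f[1]), float(f[2]))
            if fid in by_id:
                by_id[fid].crest_intervals.append(crest)
            else:
                by_id[fid] = FibreObservation(
                    fibre_id=fid,
                    crest_intervals=[crest],
                    bac_interval=(float(f[3]), float(f[4])),
                    true_homolog=int(f[5]),
                    pattern=f[6],
                )
    return list(by_id.values())


# ------------------------------------------------------------ ground truth

def write_ground_truth_json(truths: list[GroundTruth], path: str | Path) -> None:
    payload = [
        {
            "individual_id": t.individual_id,
            "domains": [list(d) for d in t.domains],
            "snp_phase": {str(k): v for k, v in t.snp_phase.items()},
            "pool_membership": {str(k): v for k, v in t.pool_membership.items()},
        }
        for t in truths
    ]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_ground_truth_json(path: str | Path) -> list[GroundTruth]:
    payload = json.loads(Path(path).read_text())
    return [
        GroundTruth(
            individual_id=t["individual_id"],
            domains=[tuple(d) for d in t["domains"]],
            snp_phase={int(k): v for k, v in t["snp_phase"].items()},
            pool_membership={int(k): v for k, v in t["pool_membership"].items()},
        )
        for t in payload
    ]
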