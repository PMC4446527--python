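"""End-to-end pipeline: peaks → phased domains → epiallele catalogue.

``phase_individual`` runs peak calling and homolog phasing for one
individual's track + markers; ``run_pipeline`` runs every individual and
pools the phased domains into a catalogue, optionally writing all stage
outputs plus a JSON manifest recording the parameters used.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as cio
from .config import PipelineConfig
from .epiallele import EpialleleCatalog, match_domains
from .peakcall import Peak, ProbeTrack, call_peaks
from .snp_phase import (
    HomologDomain,
    MarkerObservation,
    PhasingResult,
    classify_markers,
    phase_domains,
)

__all__ = ["IndividualResult", "PipelineReport", "phase_individual", "run_pipeline"]

log = logging.getLogger("cenphase")


@dataclass
class IndividualResult:
    individual_id: str
    peaks: list[Peak]
    phasing: PhasingResult

    @property
    def domains(self) -> list[HomologDomain]:
        return self.phasing.domains


@dataclass
class PipelineReport:
    individuals: list[IndividualResult]
    catalog: EpialleleCatalog
    config: PipelineConfig
    inconsistent: list[str] = field(default_factory=list)

    @property
    def all_domains(self) -> list[HomologDomain]:
        return [d for r in self.individuals for d in r.domains]


def phase_individual(
    track: ProbeTrack,
    markers: list[MarkerObservation],
    config: PipelineConfig,
) -> IndividualResult:
    """Peak calling plus marker-based homolog phasing for one individual.

    Markers falling outside every called peak carry no phasing information
    and are dropped before phasing.
    """
    peaks = call_peaks(track, q=config.q, alpha=config.alpha, max_gap_bp=config.max_gap_bp)
    in_peak = [
        m for m in markers if any(p.start <= m.pos < p.end for p in peaks)
    ]
    calls = classify_markers(
        in_peak,
        alpha=config.marker_alpha,
        mono_floor=config.mono_floor,
        bi_ceiling=config.bi_ceiling,
    )
    phasing = phase_domains(peaks, calls, individual_id=track.individual_id)
    log.info(
        "%s: %d peaks, %d in-peak markers, structure=%s",
        track.individual_id, len(peaks), len(in_peak), phasing.structure_call,
    )
    return IndividualResult(track.individual_id, peaks, phasing)


def run_pipeline(
    config: PipelineConfig,
    inputs: list[tuple[ProbeTrack, list[MarkerObservation]]],
    output_dir: str | Path | None = None,
) -> PipelineReport:
    """Run the full inference over a cohort of (track, markers) pairs.

    When ``output_dir`` is given, per-individual peak BEDs, the pooled
    phased-domain BED, the catalogue JSON and a manifest are written there.
    The report flags individuals whose marker evidence was inconsistent.
    """
    if not inputs:
        raise ValueError("no inputs: at least one (track, markers) pair required")
    results = [phase_individual(track, markers, config) for track, markers in inputs]
    catalog = match_domains(
        [d for r in results for d in r.domains],
        min_reciprocal_overlap=config.min_reciprocal_overlap,
    )
    inconsistent = [
        r.individual_id
        for r in results
        if r.phasing.structure_call in ("inconsistent", "unresolved")
    ]
    report = PipelineReport(results, catalog, config, inconsistent)

    if output_dir is not None:
        out = Path(output_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict = {
            "config": config.to_dict(),
            "individuals": {},
            "n_distinct_epialleles": catalog.n_distinct,
            "epiallele_labels": catalog.labels(),
            "inconsistent": inconsistent,
            "outputs": {},
        }
        for r in results:
            peaks_path = out / f"{r.individual_id}.peaks.bed"
            cio.write_peaks_bed(r.peaks, peaks_path)
            manifest["individuals"][r.individual_id] = {
                "n_peaks": len(r.peaks),
                "structure_call": r.phasing.structure_call,
                "overlap_interval": r.phasing.overlap_interval,
                "peaks_bed": peaks_path.name,
            }
        domains_path = out / "phased_domains.bed"
        cio.write_domains_bed(report.all_domains, domains_path)
        catalog_path = out / "epiallele_catalog.json"
        catalog_path.write_text(
            json.dumps(
                {
                    "n_distinct": catalog.n_distinct,
                    "min_reciprocal_overlap": catalog.min_reciprocal_overlap,
                    "entries": [
                        {
                            "label": e.label,
                            "representative": list(e.representative),
                            "members": [
                                {
                                    "individual_id": d.individual_id,
                                    "homolog": d.homolog,
                                    "start": d.start,
                                    "end": d.end,
                                }
                                for d in e.members
                            ],
                        }
                        for e in catalog.entries
                    ],
                },
                indent=2,
            )
            + "\n"
        )
        manifest["outputs"] = {
            "phased_domains_bed": domains_path.name,
            "catalog_json": catalog_path.name,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return report
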