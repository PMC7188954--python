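"""End-to-end analysis: load -> preprocess -> QC -> call -> summarize.

Plates are analyzed independently (shared settings), matching the batch
semantics of multi-file import; results are then concatenated, so a
12-plate batch equals 12 single-plate runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .curves import analyze_reaction
from .genotyping import call_pair, run_qc
from .model import (
    AnalysisSettings,
    CurveResult,
    Experiment,
    GenotypeCall,
    QCRecord,
    SettingsError,
)
from .semantics import infer_kits, pair_wells, parse_target_name, well_marker_set

__all__ = ["AnalysisResult", "analyze_experiment", "analyze_experiments",
           "resolve_control_marker"]


@dataclass
class AnalysisResult:
    calls: list[GenotypeCall] = field(default_factory=list)
    qc: list[QCRecord] = field(default_factory=list)
    curve_results: dict = field(default_factory=dict)  # (plate, well, target) -> CurveResult

    def extend(self, other: "AnalysisResult") -> None:
        self.calls.extend(other.calls)
        self.qc.extend(other.qc)
        self.curve_results.update(other.curve_results)

    def details_frame(self) -> pd.DataFrame:
        rows = []
        for (plate, well, target), res in self.curve_results.items():
            rows.append({
                "plate": plate, "well": well, "target": target,
                "cq": res.cq, "endpoint_rfu": res.endpoint_rfu,
                "amp_status": res.amp_status,
            })
        return pd.DataFrame(rows)


def resolve_control_marker(experiments: list[Experiment],
                           settings: AnalysisSettings) -> str:
    """Return the control marker, defaulting to the unique bare marker.

    A bare marker (no allele suffix) present in the data is the natural
    control-gene candidate; with exactly one, it is picked automatically,
    otherwise the user must name one.
    """
    if settings.control_marker:
        return settings.control_marker
    bare = set()
    for exp in experiments:
        for _plate, _well, reaction in exp.iter_reactions():
            spec = parse_target_name(reaction.target_name)
            if spec.allele is None:
                bare.add(spec.marker)
    if len(bare) == 1:
        return bare.pop()
    raise SettingsError(
        "control marker is ambiguous; pass one explicitly "
        f"(bare markers found: {sorted(bare) or 'none'})"
    )


def analyze_experiment(experiment: Experiment,
                       settings: AnalysisSettings) -> AnalysisResult:
    """Analyze one loaded file, plate by plate."""
    settings.validate()
    control = resolve_control_marker([experiment], settings)
    kits = infer_kits(experiment, control)
    out = AnalysisResult()

    for plate in experiment.plates:
        results: dict[tuple[str, str], CurveResult] = {}
        for well in plate.wells:
            for reaction in well.reactions:
                results[(well.position, reaction.target_name)] = analyze_reaction(
                    reaction, settings
                )

        # NTC contamination is assessed per kit on each plate: any amplified
        # reaction in an NTC well of a kit invalidates the whole kit there
        contaminated: set[str] = set()
        for well in plate.wells:
            if not well.is_ntc or not well.reactions:
                continue
            kit_id = "|".join(sorted(well_marker_set(well)))
            if any(results[(well.position, r.target_name)].amp_status == "ok"
                   for r in well.reactions):
                contaminated.add(kit_id)

        plate_pairs = []
        plate_unpaired = []
        for kit in kits:
            outcome = pair_wells(plate, kit)
            plate_pairs.extend(outcome.pairs)
            plate_unpaired.extend(outcome.unpaired)

        local_settings = settings if settings.control_marker else None
        if local_settings is None:
            from dataclasses import replace
            local_settings = replace(settings, control_marker=control)

        qc = run_qc(plate_pairs, results, local_settings,
                    ntc_contaminated_kits=contaminated,
                    unpaired=plate_unpaired, plate_id=plate.plate_id)

        calls = _plate_calls(plate_pairs, plate_unpaired, qc, results,
                             local_settings, plate.plate_id)

        out.qc.extend(qc[k] for k in sorted(qc))
        out.calls.extend(calls)
        for (pos, tgt), res in results.items():
            out.curve_results[(plate.plate_id, pos, tgt)] = res
    return out


def _plate_calls(pairs, unpaired, qc, results, settings, plate_id):
    calls: list[GenotypeCall] = []
    # replicate pairs of one (sample, kit) must agree; conflict -> NA
    by_group: dict[tuple[str, str], list] = {}
    for pair in pairs:
        by_group.setdefault((pair.sample_name, pair.kit.kit_id), []).append(pair)
    for (sample, _kit_id), group in sorted(by_group.items()):
        per_marker: dict[str, list[GenotypeCall]] = {}
        for pair in group:
            for call in call_pair(pair, qc, results, settings):
                per_marker.setdefault(call.marker, []).append(call)
        for marker, reps in sorted(per_marker.items()):
            if len(reps) == 1:
                calls.append(reps[0])
            elif len({c.call for c in reps}) == 1:
                calls.append(reps[0])
            else:
                calls.append(GenotypeCall(
                    sample_name=sample, marker=marker, call="NA",
                    reasons=["replicate mismatch"], plate_id=plate_id,
                ))
    for sample, wells, reason in unpaired:
        markers = {
            parse_target_name(r.target_name).marker
            for w in wells for r in w.reactions
        }
        markers.discard(settings.control_marker)
        for marker in sorted(markers):
            calls.append(GenotypeCall(
                sample_name=sample, marker=marker, call="NA",
                reasons=[reason if reason != "duplicate allele layout" else "unpaired"],
                plate_id=plate_id,
            ))
    return calls


def analyze_experiments(experiments: list[Experiment],
                        settings: AnalysisSettings) -> AnalysisResult:
    """Analyze a batch of files with shared settings and join the results."""
    from dataclasses import replace

    control = resolve_control_marker(experiments, settings)
    shared = replace(settings, control_marker=control)
    out = AnalysisResult()
    for exp in experiments:
        out.extend(analyze_experiment(exp, shared))
    return out
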