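"""Quality control codes and genotype calling for paired AS-qPCR wells.

Every analyzed reaction gets seven QC codes:

- RFU_QC        Low  — endpoint fluorescence below the RFU threshold
- ampStatus_QC  NoAmp — no amplification detected for the curve
- replicateMatch_QC Fail — Cq spread across replicates exceeds Cq delta
- noAmpNTC_QC   Fail — an NTC well of the kit amplified (contamination)
- ctrlMarker_QC Fail — the control marker did not amplify in the well (or
                 its paired well: a well outlier excludes the pair)
- allelesDeltaCq_QC Fail — control-adjusted allele Cq difference exceeds
                 Cq delta
- kit_QC        Fail — the sample's wells for the kit could not be paired

Genotype calling gates on kit_QC, replicateMatch_QC, ctrlMarker_QC and
noAmpNTC_QC; a gated pair yields NA. For an SNP each allele reaction is then
classified as consistent-positive (amplified, Cq in range, endpoint above
threshold), cleanly negative (no amplification and endpoint below
threshold), or uncertain (the mixed states: Cq in range but endpoint low,
or Cq out of range but endpoint high). Two positives make a heterozygote,
one positive plus one clean negative a homozygote, two negatives NA, and
any uncertain reaction — or an allele Cq difference failing the
control-adjusted delta check — degrades the pair to "Uncertain". An indel
marker is "Insertion" when both wells' presence reactions are positive,
"Deletion" when both are cleanly negative, otherwise "Uncertain".
"""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from .model import (
    FAIL,
    LOW,
    NOAMP,
    OK,
    AnalysisSettings,
    CurveResult,
    GenotypeCall,
    QCRecord,
    WellPair,
)

__all__ = [
    "adjust_delta_cq",
    "run_qc",
    "reaction_state",
    "call_genotype",
    "call_pair",
    "summarize",
    "POS",
    "NEG",
    "UNC",
]

# per-reaction consistency states
POS = "pos"  # amplified, Cq in range, endpoint above threshold
NEG = "neg"  # no amplification and endpoint below threshold
UNC = "unc"  # any mixed state


ResultKey = tuple[str, str]  # (well position, target name)


def adjust_delta_cq(cq_allele_a, cq_allele_b, cq_ctrl_a, cq_ctrl_b) -> float | None:
    """Control-gene-adjusted allele Cq difference for a well pair.

    The allele Cq difference is normalized by the control-gene Cq difference
    of the same two wells, cancelling per-well DNA-load offsets:

        adjusted = |(Cq_a - Cq_b) - (Cq_ctrl_a - Cq_ctrl_b)|

    If either control Cq is missing the raw |Cq_a - Cq_b| is used; if either
    allele Cq is missing there is nothing to compare and None is returned.
    """
    if cq_allele_a is None or cq_allele_b is None:
        return None
    delta = cq_allele_a - cq_allele_b
    if cq_ctrl_a is not None and cq_ctrl_b is not None:
        delta -= cq_ctrl_a - cq_ctrl_b
    return abs(delta)


def _control_cq(pair: WellPair, well, results: dict[ResultKey, CurveResult],
                control_marker: str) -> float | None:
    r = well.reaction_for(control_marker)
    if r is None:
        return None
    res = results.get((well.position, control_marker))
    return None if res is None else res.cq


def run_qc(
    pairs: list[WellPair],
    results: dict[ResultKey, CurveResult],
    settings: AnalysisSettings,
    *,
    ntc_contaminated_kits: set[str] = frozenset(),
    unpaired: list[tuple[str, list, str]] = (),
    plate_id: str = "",
) -> dict[ResultKey, QCRecord]:
    """Assign all QC codes for one plate's paired and unpaired reactions.

    ``results`` maps (well position, target name) to the reaction's
    CurveResult. ``ntc_contaminated_kits`` lists kit ids whose NTC wells
    amplified on this plate; every reaction of those kits fails
    noAmpNTC_QC. Unpaired samples' reactions fail kit_QC.
    """
    records: dict[ResultKey, QCRecord] = {}

    def record(well, target) -> QCRecord:
        key = (well.position, target)
        if key not in records:
            res = results.get(key)
            rec = QCRecord(
                plate_id=plate_id,
                position=well.position,
                sample_name=well.sample_name,
                target_name=target,
            )
            if res is not None:
                if res.endpoint_rfu < settings.rfu_threshold:
                    rec.RFU_QC = LOW
                if res.amp_status != "ok":
                    rec.ampStatus_QC = NOAMP
            records[key] = rec
        return records[key]

    ctrl = settings.control_marker

    for pair in pairs:
        wells = (pair.well_a, pair.well_b)
        ctrl_fail = False
        for well in wells:
            for rxn in well.reactions:
                record(well, rxn.target_name)
            if ctrl is not None:
                res = results.get((well.position, ctrl))
                if res is None or res.amp_status != "ok":
                    ctrl_fail = True
        if ctrl_fail:
            # a control failure in either well excludes the whole pair
            for well in wells:
                for rxn in well.reactions:
                    record(well, rxn.target_name).ctrlMarker_QC = FAIL
        if pair.kit.kit_id in ntc_contaminated_kits:
            for well in wells:
                for rxn in well.reactions:
                    record(well, rxn.target_name).noAmpNTC_QC = FAIL
        _alleles_delta_qc(pair, results, settings, record)

    _replicate_qc(pairs, results, settings, record)

    from .semantics import well_marker_set

    for sample_name, wells, _reason in unpaired:
        for well in wells:
            kit_id = "|".join(sorted(well_marker_set(well)))
            for rxn in well.reactions:
                rec = record(well, rxn.target_name)
                rec.kit_QC = FAIL
                if kit_id in ntc_contaminated_kits:
                    rec.noAmpNTC_QC = FAIL
    return records


def _alleles_delta_qc(pair, results, settings, record) -> None:
    ctrl = settings.control_marker
    ctrl_a = _control_cq(pair, pair.well_a, results, ctrl) if ctrl else None
    ctrl_b = _control_cq(pair, pair.well_b, results, ctrl) if ctrl else None
    for marker, amap in pair.allele_map.items():
        if "+" in amap:
            continue
        (al_a, pos_a), (al_b, pos_b) = sorted(amap.items())
        res_a = results.get((pos_a, f"{marker}_{al_a}"))
        res_b = results.get((pos_b, f"{marker}_{al_b}"))
        cq_a = res_a.cq if res_a else None
        cq_b = res_b.cq if res_b else None
        if pos_a == pair.well_a.position:
            adj = adjust_delta_cq(cq_a, cq_b, ctrl_a, ctrl_b)
        else:
            adj = adjust_delta_cq(cq_a, cq_b, ctrl_b, ctrl_a)
        if adj is not None and adj > settings.cq_delta:
            for pos, tgt in ((pos_a, f"{marker}_{al_a}"), (pos_b, f"{marker}_{al_b}")):
                well = pair.well_a if pos == pair.well_a.position else pair.well_b
                record(well, tgt).allelesDeltaCq_QC = FAIL


def _replicate_qc(pairs, results, settings, record) -> None:
    """Compare Cq across replicate pairs (same sample, same kit)."""
    groups: dict[tuple[str, str], list[WellPair]] = defaultdict(list)
    for p in pairs:
        groups[(p.sample_name, p.kit.kit_id)].append(p)
    for reps in groups.values():
        if len(reps) < 2:
            continue
        by_target: dict[str, list[tuple]] = defaultdict(list)
        for p in reps:
            for well in (p.well_a, p.well_b):
                for rxn in well.reactions:
                    res = results.get((well.position, rxn.target_name))
                    if res is not None and res.cq is not None:
                        by_target[rxn.target_name].append((well, res.cq))
        for target, entries in by_target.items():
            if len(entries) < 2:
                continue
            cqs = [cq for _, cq in entries]
            if max(cqs) - min(cqs) > settings.cq_delta:
                for p in reps:
                    for well in (p.well_a, p.well_b):
                        if well.reaction_for(target) is not None:
                            record(well, target).replicateMatch_QC = FAIL


def reaction_state(result: CurveResult | None, settings: AnalysisSettings) -> str:
    """Classify one allele reaction as positive, negative or uncertain."""
    if result is None:
        return UNC
    amplified = result.amp_status == "ok"
    high_rfu = result.endpoint_rfu >= settings.rfu_threshold
    lo, hi = settings.cq_range
    in_range = result.cq is not None and lo <= result.cq <= hi
    if amplified and in_range and high_rfu:
        return POS
    if not amplified and not high_rfu:
        return NEG
    return UNC


_GATE_CODES = ("kit_QC", "replicateMatch_QC", "ctrlMarker_QC", "noAmpNTC_QC")


def _gate_reasons(records: list[QCRecord]) -> list[str]:
    reasons = []
    for code in _GATE_CODES:
        if any(getattr(rec, code) != OK for rec in records):
            reasons.append(code)
    return reasons


def call_genotype(
    pair: WellPair,
    marker: str,
    qc: dict[ResultKey, QCRecord],
    results: dict[ResultKey, CurveResult],
    settings: AnalysisSettings,
) -> GenotypeCall:
    """Call the genotype of one marker for one well pair.

    Gate first: any failure of kit_QC, replicateMatch_QC, ctrlMarker_QC or
    noAmpNTC_QC on the pair's reactions for this marker (or its control
    reactions) yields NA. Then apply the SNP or indel decision table over
    the per-reaction states.
    """
    amap = pair.allele_map.get(marker, {})
    is_indel = "+" in amap
    ctrl = settings.control_marker

    if is_indel:
        targets = [(pair.well_a, f"{marker}_+"), (pair.well_b, f"{marker}_+")]
    else:
        targets = []
        for allele, pos in sorted(amap.items()):
            well = pair.well_a if pos == pair.well_a.position else pair.well_b
            targets.append((well, f"{marker}_{allele}"))

    gate_records = [qc[(w.position, t)] for w, t in targets if (w.position, t) in qc]
    if ctrl is not None:
        for well in (pair.well_a, pair.well_b):
            key = (well.position, ctrl)
            if key in qc:
                gate_records.append(qc[key])
    gate = _gate_reasons(gate_records)

    cq_values: dict[str, float | None] = {}
    states: list[str] = []
    for well, target in targets:
        res = results.get((well.position, target))
        label = target.rsplit("_", 1)[1] if not is_indel else f"+{well.position}"
        cq_values[label] = res.cq if res else None
        states.append(reaction_state(res, settings))

    adjusted = None
    if not is_indel and len(targets) == 2:
        ctrl_cqs = {}
        for well in (pair.well_a, pair.well_b):
            resc = results.get((well.position, ctrl)) if ctrl else None
            ctrl_cqs[well.position] = resc.cq if resc else None
        (w0, t0), (w1, t1) = targets
        r0, r1 = results.get((w0.position, t0)), results.get((w1.position, t1))
        adjusted = adjust_delta_cq(
            r0.cq if r0 else None,
            r1.cq if r1 else None,
            ctrl_cqs[w0.position],
            ctrl_cqs[w1.position],
        )

    base = dict(sample_name=pair.sample_name, marker=marker,
                cq_values=cq_values, adjusted_delta=adjusted,
                plate_id=pair.plate_id)

    if gate:
        return GenotypeCall(call="NA", reasons=gate, **base)

    if is_indel:
        if all(s == POS for s in states):
            return GenotypeCall(call="Insertion", **base)
        if all(s == NEG for s in states):
            return GenotypeCall(call="Deletion", **base)
        return GenotypeCall(call="Uncertain",
                            reasons=_uncertain_reasons(targets, qc, states), **base)

    alleles = sorted(amap)
    if len(states) != 2:
        return GenotypeCall(call="NA", reasons=["kit_QC"], **base)
    sa, sb = states
    if sa == POS and sb == POS:
        delta_fail = any(
            qc[(w.position, t)].allelesDeltaCq_QC != OK
            for w, t in targets if (w.position, t) in qc
        )
        if delta_fail:
            return GenotypeCall(call="Uncertain", reasons=["allelesDeltaCq_QC"], **base)
        return GenotypeCall(call=f"{alleles[0]}/{alleles[1]}", **base)
    if {sa, sb} == {POS, NEG}:
        hom = alleles[0] if sa == POS else alleles[1]
        return GenotypeCall(call=f"{hom}/{hom}", **base)
    if sa == NEG and sb == NEG:
        return GenotypeCall(call="NA", reasons=["no signal"], **base)
    return GenotypeCall(call="Uncertain",
                        reasons=_uncertain_reasons(targets, qc, states), **base)


def _uncertain_reasons(targets, qc, states) -> list[str]:
    reasons = []
    for (well, target), state in zip(targets, states):
        if state != UNC:
            continue
        rec = qc.get((well.position, target))
        if rec is None:
            reasons.append(f"{target}: missing result")
            continue
        if rec.RFU_QC != OK:
            reasons.append(f"{target}: RFU_QC=Low")
        elif rec.ampStatus_QC == OK:
            reasons.append(f"{target}: Cq out of range")
        else:
            reasons.append(f"{target}: ambiguous signal")
    return reasons or ["inconsistent reactions"]


def call_pair(pair: WellPair, qc, results, settings) -> list[GenotypeCall]:
    """All marker calls for one well pair (control marker excluded)."""
    calls = []
    for marker in sorted(pair.allele_map):
        calls.append(call_genotype(pair, marker, qc, results, settings))
    return calls


def summarize(calls: list[GenotypeCall]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-marker genotype counts and the per-sample wide results table.

    NA is counted as its own category. When the same (sample, marker) was
    called on several plates the calls are kept per plate in the long data
    but the wide table takes the first non-NA call.
    """
    if not calls:
        return (pd.DataFrame(columns=["marker", "call", "count"]),
                pd.DataFrame())
    long = pd.DataFrame(
        [
            {"sample": c.sample_name, "marker": c.marker, "call": c.call,
             "plate": c.plate_id}
            for c in calls
        ]
    )
    counts = (
        long.groupby(["marker", "call"]).size().reset_index(name="count")
        .sort_values(["marker", "call"], ignore_index=True)
    )

    def pick(series: pd.Series) -> str:
        non_na = [v for v in series if v != "NA"]
        return non_na[0] if non_na else series.iloc[0]

    wide = (
        long.pivot_table(index="sample", columns="marker", values="call",
                         aggfunc=pick)
        .sort_index()
    )
    wide.columns.name = None
    return counts, wide
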