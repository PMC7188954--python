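"""QC codes and genotype-calling rules, checked against brute-force oracles."""

import itertools
from dataclasses import replace

import numpy as np
import pytest

import allelecall as ac
from allelecall.genotyping import (
    NEG,
    POS,
    UNC,
    adjust_delta_cq,
    call_genotype,
    reaction_state,
    run_qc,
    summarize,
)
from allelecall.model import (
    FAIL,
    OK,
    CurveResult,
    GenotypeCall,
    KitSpec,
    QCRecord,
    Reaction,
    Well,
    WellPair,
)

# ---------------------------------------------------------------------------
# synthetic per-reaction results for each named consistency state


def _result(state: str) -> CurveResult:
    cycles = np.arange(1, 41)
    table = {
        POS: dict(cq=20.0, endpoint=1000.0, amp="ok"),
        "unc_low_rfu": dict(cq=20.0, endpoint=100.0, amp="ok"),
        "unc_range": dict(cq=30.0, endpoint=1000.0, amp="ok"),
        NEG: dict(cq=None, endpoint=5.0, amp="no_amp"),
    }[state]
    return CurveResult(corrected_rfu=np.zeros(40), cycles=cycles, fit=None,
                       cq=table["cq"], endpoint_rfu=table["endpoint"],
                       amp_status=table["amp"])


STATE_NAMES = (POS, "unc_low_rfu", "unc_range", NEG)


def _snp_pair(sample="p894"):
    wa = Well("A01", sample, reactions=[
        Reaction("HER2_C", "FAM", np.arange(1, 41), np.zeros(40)),
        Reaction("B2m", "Cy5", np.arange(1, 41), np.zeros(40)),
    ])
    wb = Well("A02", sample, reactions=[
        Reaction("HER2_G", "FAM", np.arange(1, 41), np.zeros(40)),
        Reaction("B2m", "Cy5", np.arange(1, 41), np.zeros(40)),
    ])
    kit = KitSpec("B2m|HER2", frozenset({"B2m", "HER2"}), "B2m")
    return WellPair(sample_name=sample, kit=kit, well_a=wa, well_b=wb,
                    allele_map={"HER2": {"C": "A01", "G": "A02"}}, plate_id="p")


def _indel_pair(sample="p894"):
    wa = Well("A01", sample, reactions=[
        Reaction("UGT2b17_+", "FAM", np.arange(1, 41), np.zeros(40)),
        Reaction("B2m", "Cy5", np.arange(1, 41), np.zeros(40)),
    ])
    wb = Well("A02", sample, reactions=[
        Reaction("UGT2b17_+", "FAM", np.arange(1, 41), np.zeros(40)),
        Reaction("B2m", "Cy5", np.arange(1, 41), np.zeros(40)),
    ])
    kit = KitSpec("B2m|UGT2b17", frozenset({"B2m", "UGT2b17"}), "B2m")
    return WellPair(sample_name=sample, kit=kit, well_a=wa, well_b=wb,
                    allele_map={"UGT2b17": {"+": "both"}}, plate_id="p")


def _assemble(pair, state_a, state_b, gates, marker_targets):
    """Build the results and QC maps for one enumeration cell."""
    results = {
        (pair.well_a.position, "B2m"): _result(POS),
        (pair.well_b.position, "B2m"): _result(POS),
        marker_targets[0]: _result(state_a),
        marker_targets[1]: _result(state_b),
    }
    qc = {}
    for (pos, tgt), res in results.items():
        rec = QCRecord(plate_id="p", position=pos, sample_name=pair.sample_name,
                       target_name=tgt)
        if res.endpoint_rfu < 200.0:
            rec.RFU_QC = "Low"
        if res.amp_status != "ok":
            rec.ampStatus_QC = "NoAmp"
        for code, failed in gates.items():
            if failed:
                setattr(rec, code, FAIL)
        qc[(pos, tgt)] = rec
    return results, qc


def _oracle_snp(state_a, state_b, any_gate):
    """Independent enumeration of the SNP decision table (alleles C < G)."""
    if any_gate:
        return "NA"
    simple = {POS: POS, NEG: NEG, "unc_low_rfu": UNC, "unc_range": UNC}
    sa, sb = simple[state_a], simple[state_b]
    if sa == POS and sb == POS:
        return "C/G"
    if sa == POS and sb == NEG:
        return "C/C"
    if sa == NEG and sb == POS:
        return "G/G"
    if sa == NEG and sb == NEG:
        return "NA"
    return "Uncertain"


def _oracle_indel(state_a, state_b, any_gate):
    if any_gate:
        return "NA"
    simple = {POS: POS, NEG: NEG, "unc_low_rfu": UNC, "unc_range": UNC}
    sa, sb = simple[state_a], simple[state_b]
    if sa == POS and sb == POS:
        return "Insertion"
    if sa == NEG and sb == NEG:
        return "Deletion"
    return "Uncertain"


GATE_CODES = ("kit_QC", "replicateMatch_QC", "ctrlMarker_QC", "noAmpNTC_QC")


class TestTruthTable:
    @pytest.mark.parametrize("gate_combo", list(itertools.product([False, True],
                                                                  repeat=4)))
    def test_snp_decision_table(self, settings, gate_combo):
        """call_genotype matches the brute-force SNP enumeration, all cells."""
        gates = dict(zip(GATE_CODES, gate_combo))
        pair = _snp_pair()
        targets = (("A01", "HER2_C"), ("A02", "HER2_G"))
        for state_a, state_b in itertools.product(STATE_NAMES, repeat=2):
            results, qc = _assemble(pair, state_a, state_b, gates, targets)
            got = call_genotype(pair, "HER2", qc, results, settings)
            assert got.call == _oracle_snp(state_a, state_b, any(gate_combo)), (
                state_a, state_b, gates)

    @pytest.mark.parametrize("gate_combo", list(itertools.product([False, True],
                                                                  repeat=4)))
    def test_indel_decision_table(self, settings, gate_combo):
        gates = dict(zip(GATE_CODES, gate_combo))
        pair = _indel_pair()
        targets = (("A01", "UGT2b17_+"), ("A02", "UGT2b17_+"))
        for state_a, state_b in itertools.product(STATE_NAMES, repeat=2):
            results, qc = _assemble(pair, state_a, state_b, gates, targets)
            got = call_genotype(pair, "UGT2b17", qc, results, settings)
            assert got.call == _oracle_indel(state_a, state_b, any(gate_combo)), (
                state_a, state_b, gates)

    def test_monotone_safety(self, settings):
        """Worsening any single QC code never upgrades a call to definite."""
        definite = lambda c: c not in ("NA", "Uncertain")
        pair = _snp_pair()
        targets = (("A01", "HER2_C"), ("A02", "HER2_G"))
        for state_a, state_b in itertools.product(STATE_NAMES, repeat=2):
            results, qc = _assemble(pair, state_a, state_b,
                                    dict.fromkeys(GATE_CODES, False), targets)
            baseline = call_genotype(pair, "HER2", qc, results, settings).call
            for key in qc:
                for code in QCRecord.CODE_FIELDS:
                    if getattr(qc[key], code) != OK:
                        continue
                    worse = {k: replace(v) for k, v in qc.items()}
                    setattr(worse[key], code,
                            "Low" if code == "RFU_QC"
                            else "NoAmp" if code == "ampStatus_QC" else FAIL)
                    after = call_genotype(pair, "HER2", worse, results,
                                          settings).call
                    if not definite(baseline):
                        assert not definite(after), (state_a, state_b, key, code)


class TestDeltaCq:
    def test_zero_control_offset(self):
        assert adjust_delta_cq(20.0, 23.0, 18.0, 18.0) == pytest.approx(3.0)

    def test_control_offset_subtracted(self):
        assert adjust_delta_cq(20.0, 24.0, 18.0, 19.0) == pytest.approx(3.0)

    def test_missing_control_falls_back_to_raw(self):
        assert adjust_delta_cq(20.0, 24.0, None, 19.0) == pytest.approx(4.0)

    def test_missing_allele_cq_yields_none(self):
        assert adjust_delta_cq(None, 24.0, 18.0, 19.0) is None

    def test_invariant_to_shared_load_shift(self):
        """A well-wide Cq shift moves allele and control alike: delta fixed."""
        base = adjust_delta_cq(20.0, 20.5, 18.0, 18.2)
        for shift in (0.5, 1.0, 3.0):
            shifted = adjust_delta_cq(20.0 + shift, 20.5, 18.0 + shift, 18.2)
            assert shifted == pytest.approx(base)


class TestRunQC:
    def test_low_endpoint_flags_rfu_qc(self, settings):
        pair = _snp_pair()
        targets = (("A01", "HER2_C"), ("A02", "HER2_G"))
        results, _ = _assemble(pair, "unc_low_rfu", POS,
                               dict.fromkeys(GATE_CODES, False), targets)
        qc = run_qc([pair], results, settings)
        assert qc[("A01", "HER2_C")].RFU_QC == "Low"
        assert qc[("A02", "HER2_G")].RFU_QC == OK

    def test_control_failure_propagates_to_both_wells(self, settings):
        pair = _snp_pair()
        targets = (("A01", "HER2_C"), ("A02", "HER2_G"))
        results, _ = _assemble(pair, POS, POS,
                               dict.fromkeys(GATE_CODES, False), targets)
        results[("A01", "B2m")] = _result(NEG)  # control dead in one well
        qc = run_qc([pair], results, settings)
        for key in targets:
            assert qc[key].ctrlMarker_QC == FAIL
        assert qc[("A02", "B2m")].ctrlMarker_QC == FAIL

    def test_ntc_contamination_fails_whole_kit(self, settings):
        pair = _snp_pair()
        targets = (("A01", "HER2_C"), ("A02", "HER2_G"))
        results, _ = _assemble(pair, POS, POS,
                               dict.fromkeys(GATE_CODES, False), targets)
        qc = run_qc([pair], results, settings,
                    ntc_contaminated_kits={"B2m|HER2"})
        assert all(qc[k].noAmpNTC_QC == FAIL for k in targets)

    def test_alleles_delta_uses_control_adjustment(self, settings):
        pair = _snp_pair()
        results = {
            ("A01", "HER2_C"): _result(POS),
            ("A02", "HER2_G"): _result(POS),
            ("A01", "B2m"): _result(POS),
            ("A02", "B2m"): _result(POS),
        }
        # raw allele delta 4.0 would fail, but the control shows the same
        # 4-cycle load offset, so the adjusted delta is 0
        results[("A01", "HER2_C")].cq = 24.0
        results[("A01", "B2m")].cq = 24.0
        results[("A02", "HER2_G")].cq = 20.0
        results[("A02", "B2m")].cq = 20.0
        qc = run_qc([pair], results, settings)
        assert qc[("A01", "HER2_C")].allelesDeltaCq_QC == OK
        # and without the control shift it genuinely fails
        results[("A01", "B2m")].cq = 20.0
        qc = run_qc([pair], results, settings)
        assert qc[("A01", "HER2_C")].allelesDeltaCq_QC == FAIL

    def test_replicate_mismatch_flagged(self, settings):
        pair1 = _snp_pair()
        wa = Well("B01", "p894", reactions=pair1.well_a.reactions)
        wb = Well("B02", "p894", reactions=pair1.well_b.reactions)
        pair2 = WellPair(sample_name="p894", kit=pair1.kit, well_a=wa,
                         well_b=wb, allele_map={"HER2": {"C": "B01", "G": "B02"}},
                         plate_id="p")
        results = {}
        for pos in ("A01", "B01"):
            results[(pos, "HER2_C")] = _result(POS)
            results[(pos, "B2m")] = _result(POS)
        for pos in ("A02", "B02"):
            results[(pos, "HER2_G")] = _result(POS)
            results[(pos, "B2m")] = _result(POS)
        results[("B01", "HER2_C")].cq = 25.0  # 5 cycles off its replicate
        qc = run_qc([pair1, pair2], results, settings)
        assert qc[("A01", "HER2_C")].replicateMatch_QC == FAIL
        assert qc[("B01", "HER2_C")].replicateMatch_QC == FAIL
        assert qc[("A02", "HER2_G")].replicateMatch_QC == OK


class TestCallExamples:
    def _call(self, settings, state_a, state_b):
        pair = _snp_pair()
        targets = (("A01", "HER2_C"), ("A02", "HER2_G"))
        results, qc = _assemble(pair, state_a, state_b,
                                dict.fromkeys(GATE_CODES, False), targets)
        return call_genotype(pair, "HER2", qc, results, settings)

    def test_heterozygote(self, settings):
        assert self._call(settings, POS, POS).call == "C/G"

    def test_homozygote(self, settings):
        assert self._call(settings, POS, NEG).call == "C/C"

    def test_uncertain_low_rfu_in_range(self, settings):
        assert self._call(settings, "unc_low_rfu", POS).call == "Uncertain"

    def test_deletion(self, settings):
        pair = _indel_pair()
        targets = (("A01", "UGT2b17_+"), ("A02", "UGT2b17_+"))
        results, qc = _assemble(pair, NEG, NEG,
                                dict.fromkeys(GATE_CODES, False), targets)
        got = call_genotype(pair, "UGT2b17", qc, results, settings)
        assert got.call == "Deletion"


class TestSummarize:
    def test_counts_and_wide_table(self):
        calls = [
            GenotypeCall("s1", "HER2", "C/G"),
            GenotypeCall("s2", "HER2", "C/G"),
            GenotypeCall("s3", "HER2", "C/G"),
            GenotypeCall("s1", "KRAS", "NA", reasons=["kit_QC"]),
        ]
        counts, wide = summarize(calls)
        row = counts[(counts.marker == "HER2") & (counts.call == "C/G")]
        assert row["count"].item() == 3
        assert counts[counts.call == "NA"]["count"].item() == 1
        assert wide.loc["s1", "HER2"] == "C/G"
        assert wide.loc["s1", "KRAS"] == "NA"

    def test_empty_calls(self):
        counts, wide = summarize([])
        assert counts.empty and wide.empty
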