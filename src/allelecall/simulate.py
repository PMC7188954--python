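"""Synthetic AS-qPCR study generator with known ground truth.

The default design mirrors a production minor-histocompatibility-antigen
panel: 96 DNA samples over twelve 96-well plates, 8 samples per plate, the
20 targets (19 SNP markers + 1 indel marker) split into five kits of paired
wells, five detection channels per well (four target markers plus the B2m
control gene). One plate therefore carries 8 samples x 5 kits x 2 wells x 5
channels = 400 reactions, 4,800 across the study, with 96 x 20 = 1,920
possible target genotype calls; a fully loaded plate would hold 96 x 5 =
480 reactions.

Each simulated curve is a four-parameter logistic plus a linear baseline
drift and i.i.d. Gaussian noise; negative reactions carry baseline, drift
and noise only. Genotypes are drawn under Hardy-Weinberg proportions at a
configurable allele frequency. DNA-load variation is modeled as a per-sample
Cq offset shared by all the sample's reactions plus a smaller per-well
pipetting jitter — the jitter is exactly what the control-gene Cq
adjustment must cancel. Defect injection mutates labeled reactions so QC
sensitivity is measurable against the truth table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .curves import model_predict
from .model import DesignError, Experiment, Plate, Reaction, Well

__all__ = [
    "KitTemplate",
    "PanelDesign",
    "NoiseProfile",
    "TruthTable",
    "default_design",
    "simulate_curve",
    "simulate_experiment",
    "inject_defects",
    "DEFECT_CLASSES",
]

DYES = ("FAM", "HEX", "TexasRed", "Cy5", "Quasar705")

DEFECT_CLASSES = (
    "low_rfu",
    "ntc_contamination",
    "missing_control",
    "evaporation",
    "load_imbalance",
    "late_rise",
)


@dataclass(frozen=True)
class KitTemplate:
    """Markers of one primer-mix pair; allele pairs for SNPs, "+" for indels."""

    name: str
    snps: tuple[tuple[str, tuple[str, str]], ...]  # (marker, (allele_ref, allele_alt))
    indels: tuple[str, ...] = ()


@dataclass
class PanelDesign:
    kits: tuple[KitTemplate, ...]
    control_marker: str = "B2m"
    n_samples: int = 96
    samples_per_plate: int = 8
    n_channels: int = 5
    n_cycles: int = 40
    wells_per_plate: int = 96
    ntc_layout: str = "none"  # "none" or "per_kit"

    def validate(self) -> None:
        for kit in self.kits:
            per_well = len(kit.snps) + len(kit.indels) + 1  # + control
            if per_well > self.n_channels:
                raise DesignError(
                    f"kit {kit.name}: {per_well} reactions per well exceed "
                    f"{self.n_channels} detection channels"
                )
        if self.n_samples % self.samples_per_plate:
            raise DesignError("n_samples must be a multiple of samples_per_plate")
        wells_needed = self.samples_per_plate * len(self.kits) * 2
        if self.ntc_layout == "per_kit":
            wells_needed += 2 * len(self.kits)
        if wells_needed > self.wells_per_plate:
            raise DesignError(f"{wells_needed} wells needed on a "
                              f"{self.wells_per_plate}-well plate")

    @property
    def n_plates(self) -> int:
        return self.n_samples // self.samples_per_plate

    @property
    def target_markers(self) -> list[str]:
        out = []
        for kit in self.kits:
            out.extend(m for m, _ in kit.snps)
            out.extend(kit.indels)
        return out

    @property
    def plate_capacity(self) -> int:
        """Reactions on a fully loaded plate: wells x detection channels."""
        return self.wells_per_plate * self.n_channels

    def sample_reactions_per_plate(self) -> int:
        return sum(
            self.samples_per_plate * 2 * (len(k.snps) + len(k.indels) + 1)
            for k in self.kits
        )


@dataclass
class NoiseProfile:
    """Stochastic ingredients of a simulated run.

    ``noise_sd`` is in RFU (the default 20 is 2% of the default 1000-RFU
    amplitude); ``drift_slope`` is RFU per cycle of linear baseline drift.
    """

    noise_sd: float = 20.0
    drift_slope: float = 0.5
    baseline: float = 50.0
    amplitude: float = 1000.0
    amplitude_jitter: float = 0.1
    slope_k: float = 0.8  # logistic steepness; model parameter b = -k
    cq_low: float = 18.0
    cq_high: float = 21.0
    sample_offset_sd: float = 0.5
    well_jitter_sd: float = 0.15
    het_shift: float = 1.0  # extra cycles when the allele has one copy of two
    allele_freq: float = 0.5
    deletion_freq: float = 0.5  # frequency of the deletion allele at indels


def default_design() -> PanelDesign:
    """The 5-kit, 19-SNP + 1-indel + control-gene panel on 12 plates."""
    allele_pairs = (("A", "G"), ("C", "T"), ("C", "G"), ("A", "T"))
    kits = []
    snp_i = 0
    for k in range(5):
        snps = []
        n_snps = 4 if k < 4 else 3
        for _ in range(n_snps):
            snp_i += 1
            snps.append((f"HA{snp_i:02d}", allele_pairs[(snp_i - 1) % 4]))
        indels = () if k < 4 else ("UGT2b17",)
        kits.append(KitTemplate(name=f"kit{k + 1}", snps=tuple(snps), indels=indels))
    return PanelDesign(kits=tuple(kits))


@dataclass
class TruthTable:
    """Ground truth for a simulated study.

    ``genotypes``: one row per (sample, marker) with the true call.
    ``reactions``: one row per simulated reaction with its generating
    parameters, positivity and any defect label.
    """

    genotypes: pd.DataFrame
    reactions: pd.DataFrame
    defect_log: list[dict] = field(default_factory=list)

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.genotypes.to_csv(out / "truth_genotypes.csv", index=False)
        self.reactions.to_csv(out / "truth_reactions.csv", index=False)
        pd.DataFrame(self.defect_log).to_csv(out / "truth_defects.csv", index=False)


def simulate_curve(positive: bool, params: dict, noise_sd: float,
                   drift_slope: float, n_cycles: int,
                   rng: np.random.Generator, baseline: float = 50.0) -> np.ndarray:
    """One fluorescence trace: baseline + drift (+ sigmoid) + Gaussian noise.

    ``params`` carries the logistic parameters b, d, e (c of the amplified
    component is 0; the baseline enters additively).
    """
    x = np.arange(1, n_cycles + 1, dtype=float)
    trace = baseline + drift_slope * x
    if positive:
        trace = trace + model_predict("b4", x, params["b"], 0.0, params["d"],
                                      params["e"], 1.0)
    if noise_sd > 0:
        trace = trace + rng.normal(0.0, noise_sd, size=n_cycles)
    return trace


def _draw_genotypes(design: PanelDesign, noise: NoiseProfile,
                    rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    samples = [f"s{i + 1:03d}" for i in range(design.n_samples)]
    for kit in design.kits:
        for marker, (a1, a2) in kit.snps:
            p = noise.allele_freq
            for s in samples:
                draw = rng.random(2)
                alleles = sorted(a1 if d < p else a2 for d in draw)
                call = f"{alleles[0]}/{alleles[1]}"
                rows.append({"sample": s, "marker": marker, "call": call})
        for marker in kit.indels:
            q = noise.deletion_freq
            for s in samples:
                both_deleted = (rng.random() < q) and (rng.random() < q)
                rows.append({"sample": s, "marker": marker,
                             "call": "Deletion" if both_deleted else "Insertion"})
    return pd.DataFrame(rows)


def _plate_layout(design: PanelDesign):
    """Yield (kit_index, mix_index, row_index, column) well coordinates.

    Kit k occupies column pair (2k+1, 2k+2); sample rows run A..H. NTC wells,
    when enabled, sit in columns 11-12, one row per kit.
    """
    for k in range(len(design.kits)):
        for mix in range(2):
            col = 2 * k + 1 + mix
            for row in range(design.samples_per_plate):
                yield k, mix, row, col


def simulate_experiment(
    design: PanelDesign | None = None,
    truth_seed: int = 0,
    noise: NoiseProfile | None = None,
) -> tuple[list[Experiment], TruthTable]:
    """Simulate the full study: one Experiment per plate plus the truth table.

    Genotypes are drawn first; each reaction's inflection cycle combines the
    marker's base Cq, the sample's DNA-load offset, the well's pipetting
    jitter and (for heterozygous alleles) a one-cycle single-copy shift. The
    instrument-software Cq carried in the file (preprocessed_cq) is the true
    inflection cycle of positive reactions.
    """
    design = design or default_design()
    noise = noise or NoiseProfile()
    design.validate()
    rng = np.random.default_rng(truth_seed)

    genotypes = _draw_genotypes(design, noise, rng)
    truth = genotypes.set_index(["sample", "marker"])["call"]

    base_cq = {
        m: rng.uniform(noise.cq_low, noise.cq_high) for m in design.target_markers
    }
    base_cq[design.control_marker] = rng.uniform(noise.cq_low, noise.cq_high - 1.0)
    sample_offsets = {
        f"s{i + 1:03d}": float(np.clip(rng.normal(0.0, noise.sample_offset_sd),
                                       -1.2, 1.2))
        for i in range(design.n_samples)
    }

    experiments: list[Experiment] = []
    reaction_rows: list[dict] = []

    for plate_i in range(design.n_plates):
        plate_samples = [f"s{plate_i * design.samples_per_plate + r + 1:03d}"
                         for r in range(design.samples_per_plate)]
        wells: dict[str, Well] = {}

        def add_reaction(position, sample, sample_type, target, dye, positive,
                         e_cycle, plate_id):
            amp = noise.amplitude * (
                1.0 + rng.uniform(-noise.amplitude_jitter, noise.amplitude_jitter)
            )
            params = {"b": -noise.slope_k, "d": amp, "e": e_cycle}
            trace = simulate_curve(positive, params, noise.noise_sd,
                                   noise.drift_slope, design.n_cycles, rng,
                                   baseline=noise.baseline)
            well = wells.get(position)
            if well is None:
                well = Well(position=position, sample_name=sample,
                            sample_type=sample_type)
                wells[position] = well
            well.reactions.append(Reaction(
                target_name=target, dye=dye,
                cycles=np.arange(1, design.n_cycles + 1),
                rfu=np.round(trace, 6),
                preprocessed_cq=round(e_cycle, 6) if positive else None,
            ))
            reaction_rows.append({
                "plate": plate_id, "well": position, "sample": sample,
                "target": target, "positive": positive,
                "b": params["b"], "d": params["d"], "e": params["e"],
                "baseline": noise.baseline, "drift_slope": noise.drift_slope,
                "noise_sd": noise.noise_sd, "defect": "",
            })

        plate_id = f"plate{plate_i + 1:02d}"
        for k, mix, row, col in _plate_layout(design):
            kit = design.kits[k]
            sample = plate_samples[row]
            position = f"{chr(ord('A') + row)}{col:02d}"
            well_jitter = float(np.clip(rng.normal(0.0, noise.well_jitter_sd),
                                        -0.4, 0.4))
            offset = sample_offsets[sample] + well_jitter
            dye_i = 0
            for marker, alleles in kit.snps:
                allele = alleles[mix]
                genotype = truth[(sample, marker)]
                copies = genotype.split("/").count(allele)
                positive = copies > 0
                e_cycle = base_cq[marker] + offset + (
                    noise.het_shift if copies == 1 else 0.0
                )
                add_reaction(position, sample, "unknown", f"{marker}_{allele}",
                             DYES[dye_i], positive, e_cycle, plate_id)
                dye_i += 1
            for marker in kit.indels:
                positive = truth[(sample, marker)] == "Insertion"
                e_cycle = base_cq[marker] + offset
                add_reaction(position, sample, "unknown", f"{marker}_+",
                             DYES[dye_i], positive, e_cycle, plate_id)
                dye_i += 1
            add_reaction(position, sample, "unknown", design.control_marker,
                         DYES[-1], True, base_cq[design.control_marker] + offset,
                         plate_id)

        if design.ntc_layout == "per_kit":
            for k, kit in enumerate(design.kits):
                for mix in range(2):
                    position = f"{chr(ord('A') + k)}{11 + mix:02d}"
                    dye_i = 0
                    for marker, alleles in kit.snps:
                        add_reaction(position, "NTC", "ntc",
                                     f"{marker}_{alleles[mix]}", DYES[dye_i],
                                     False, 0.0, plate_id)
                        dye_i += 1
                    for marker in kit.indels:
                        add_reaction(position, "NTC", "ntc", f"{marker}_+",
                                     DYES[dye_i], False, 0.0, plate_id)
                        dye_i += 1
                    add_reaction(position, "NTC", "ntc", design.control_marker,
                                 DYES[-1], False, 0.0, plate_id)

        plate = Plate(plate_id=plate_id,
                      wells=[wells[p] for p in sorted(wells)])
        experiments.append(Experiment(file_id=plate_id, plates=[plate],
                                      run_date="2020-01-01"))

    truth_table = TruthTable(genotypes=genotypes,
                             reactions=pd.DataFrame(reaction_rows))
    return experiments, truth_table


def _reaction_lookup(experiments):
    index = {}
    for exp in experiments:
        for plate, well, reaction in exp.iter_reactions():
            index[(plate.plate_id, well.position, reaction.target_name)] = (
                plate, well, reaction
            )
    return index


def _regenerate(reaction: Reaction, row, rng, *, positive, e_cycle=None,
                amplitude=None) -> None:
    """Rewrite a reaction's trace from its truth parameters, mutated."""
    n = len(reaction.cycles)
    params = {"b": row["b"], "d": amplitude if amplitude is not None else row["d"],
              "e": e_cycle if e_cycle is not None else row["e"]}
    trace = simulate_curve(positive, params, row["noise_sd"], row["drift_slope"],
                           n, rng, baseline=row["baseline"])
    reaction.rfu = np.round(trace, 6)
    reaction.preprocessed_cq = round(params["e"], 6) if positive else None


def inject_defects(
    experiments: list[Experiment],
    truth: TruthTable,
    defect_spec: dict[str, int] | list[str],
    rng: np.random.Generator,
    rfu_threshold: float = 200.0,
) -> None:
    """Apply labeled defects in place and record them in the truth table.

    Classes: ``low_rfu`` scales one positive target reaction's amplitude to
    half the RFU threshold; ``ntc_contamination`` turns one NTC target
    reaction positive (requires a design with NTC wells); ``missing_control``
    suppresses one well's control-gene amplification; ``evaporation`` drifts
    one well's reaction Cqs unevenly across channels (targets +6..9 cycles,
    control +0..1), the signature the control-adjusted allele delta-Cq check
    catches; ``load_imbalance`` shifts every reaction of one well by +1
    cycle uniformly (which the control adjustment must absorb);
    ``late_rise`` moves one positive reaction's transition past the last
    recorded cycle.

    Each defect entry picks a distinct random eligible reaction/well. The
    truth table's defect column and ``defect_log`` record what was mutated
    and which (sample, marker) calls it may legitimately change.
    """
    if isinstance(defect_spec, list):
        parsed: dict[str, int] = {}
        for item in defect_spec:
            name, _, count = item.partition(":")
            parsed[name] = parsed.get(name, 0) + (int(count) if count else 1)
        defect_spec = parsed
    for name in defect_spec:
        if name not in DEFECT_CLASSES:
            raise DesignError(f"unknown defect class {name!r}; "
                              f"choose from {', '.join(DEFECT_CLASSES)}")

    lookup = _reaction_lookup(experiments)
    reactions = truth.reactions
    control = _infer_control(reactions)

    def mark(idx, label, affected):
        reactions.loc[idx, "defect"] = label
        row = reactions.loc[idx]
        truth.defect_log.append({
            "class": label, "plate": row["plate"], "well": row["well"],
            "sample": row["sample"], "target": row["target"],
            "affected": ";".join(sorted({f"{s}|{m}" for s, m in affected})),
        })

    used: set[int] = set()

    def pick(mask) -> int:
        idx = reactions.index[mask & ~reactions.index.isin(used)
                              & (reactions["defect"] == "")]
        if len(idx) == 0:
            raise DesignError("no eligible reaction left for defect injection")
        choice = int(rng.choice(idx))
        used.add(choice)
        return choice

    is_target = reactions["target"] != control
    is_sample = reactions["sample"] != "NTC"

    for name, count in defect_spec.items():
        for _ in range(count):
            if name == "low_rfu":
                idx = pick(reactions["positive"] & is_target & is_sample)
                row = reactions.loc[idx]
                _, _, rxn = lookup[(row["plate"], row["well"], row["target"])]
                # amplifies visibly (above the detection noise floor) but
                # tops out at half the reporting threshold
                _regenerate(rxn, row, rng, positive=True,
                            amplitude=0.5 * rfu_threshold)
                marker = row["target"].rsplit("_", 1)[0]
                mark(idx, "low_rfu", {(row["sample"], marker)})
            elif name == "ntc_contamination":
                ntc = reactions["sample"] == "NTC"
                if not ntc.any():
                    raise DesignError(
                        "ntc_contamination needs a design with NTC wells "
                        "(ntc_layout='per_kit')"
                    )
                idx = pick(ntc & is_target)
                row = reactions.loc[idx]
                _, _, rxn = lookup[(row["plate"], row["well"], row["target"])]
                _regenerate(rxn, row, rng, positive=True, e_cycle=20.0)
                affected = _kit_scope(reactions, row, control)
                mark(idx, "ntc_contamination", affected)
            elif name == "missing_control":
                idx = pick((reactions["target"] == control) & is_sample)
                row = reactions.loc[idx]
                _, _, rxn = lookup[(row["plate"], row["well"], row["target"])]
                _regenerate(rxn, row, rng, positive=False)
                affected = _well_scope(reactions, row, control)
                mark(idx, "missing_control", affected)
            elif name == "evaporation":
                idx = pick((reactions["target"] == control) & is_sample
                           & _has_het_marker(reactions, truth, control))
                anchor = reactions.loc[idx]
                affected = _well_scope(reactions, anchor, control)
                well_mask = ((reactions["plate"] == anchor["plate"])
                             & (reactions["well"] == anchor["well"]))
                for j in reactions.index[well_mask]:
                    row = reactions.loc[j]
                    if not row["positive"]:
                        continue
                    drift = (rng.uniform(0.0, 1.0) if row["target"] == control
                             else rng.uniform(6.0, 9.0))
                    _, _, rxn = lookup[(row["plate"], row["well"], row["target"])]
                    _regenerate(rxn, row, rng, positive=True,
                                e_cycle=row["e"] + drift)
                    used.add(int(j))
                mark(idx, "evaporation", affected)
            elif name == "load_imbalance":
                idx = pick((reactions["target"] == control) & is_sample)
                anchor = reactions.loc[idx]
                well_mask = ((reactions["plate"] == anchor["plate"])
                             & (reactions["well"] == anchor["well"]))
                for j in reactions.index[well_mask]:
                    row = reactions.loc[j]
                    if not row["positive"]:
                        continue
                    _, _, rxn = lookup[(row["plate"], row["well"], row["target"])]
                    _regenerate(rxn, row, rng, positive=True,
                                e_cycle=row["e"] + 1.0)
                    used.add(int(j))
                mark(idx, "load_imbalance", set())
            elif name == "late_rise":
                idx = pick(reactions["positive"] & is_target & is_sample)
                row = reactions.loc[idx]
                plate, _, rxn = lookup[(row["plate"], row["well"], row["target"])]
                n_cycles = len(rxn.cycles)
                _regenerate(rxn, row, rng, positive=True,
                            e_cycle=float(n_cycles + 2))
                rxn.preprocessed_cq = None
                marker = row["target"].rsplit("_", 1)[0]
                mark(idx, "late_rise", {(row["sample"], marker)})


def _infer_control(reactions: pd.DataFrame) -> str:
    bare = [t for t in reactions["target"].unique() if "_" not in t]
    return bare[0] if bare else ""


def _kit_scope(reactions, row, control):
    """(sample, marker) calls invalidated by a kit-wide defect on a plate."""
    well_targets = set(
        reactions.loc[(reactions["plate"] == row["plate"])
                      & (reactions["well"] == row["well"]), "target"]
    )
    markers = {t.rsplit("_", 1)[0] for t in well_targets if t != control}
    plate_mask = reactions["plate"] == row["plate"]
    affected = set()
    for _, r in reactions.loc[plate_mask & (reactions["sample"] != "NTC")].iterrows():
        if r["target"] == control:
            continue
        m = r["target"].rsplit("_", 1)[0]
        if m in markers:
            affected.add((r["sample"], m))
    return affected


def _well_scope(reactions, row, control):
    """(sample, marker) calls of the defective well's kit wells for the sample."""
    well_mask = ((reactions["plate"] == row["plate"])
                 & (reactions["well"] == row["well"]))
    markers = {
        t.rsplit("_", 1)[0]
        for t in reactions.loc[well_mask, "target"] if t != control
    }
    return {(row["sample"], m) for m in markers}


def _has_het_marker(reactions, truth, control):
    """Mask of control reactions in wells whose sample is het for >= 1 marker."""
    het = set()
    for _, g in truth.genotypes.iterrows():
        if "/" in g["call"]:
            a, b = g["call"].split("/")
            if a != b:
                het.add((g["sample"], g["marker"]))
    mask = []
    by_well = reactions.groupby(["plate", "well"])["target"].apply(set)
    for _, row in reactions.iterrows():
        if row["target"] != control or row["sample"] == "NTC":
            mask.append(False)
            continue
        targets = by_well[(row["plate"], row["well"])]
        markers = {t.rsplit("_", 1)[0] for t in targets if t != control}
        mask.append(any((row["sample"], m) in het for m in markers))
    return pd.Series(mask, index=reactions.index)
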