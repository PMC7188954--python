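"""Plate semantics: target-name convention, kit inference and well pairing.

The naming convention is the contract between the wet lab and the caller:
target names follow the GENENAME_ALLELENAME pattern ("HER2_C" is gene HER2,
allele C); indel targets use "+" as the allele ("UGT2b17_+"); a target name
without an allele suffix is a bare marker, typically the control gene
("B2m"). Wells sharing an identical marker set form one kit, and within a
kit the two wells of one sample (equal sample names) are the allele pair.
"""

from __future__ import annotations

from collections import defaultdict

from .model import (
    Experiment,
    KitSpec,
    MarkerSpec,
    NamingError,
    Plate,
    Well,
    WellPair,
)

__all__ = [
    "parse_target_name",
    "render_target_name",
    "well_marker_set",
    "infer_kits",
    "pair_wells",
    "PairingOutcome",
]


def parse_target_name(name: str) -> MarkerSpec:
    """Split a target name into marker and allele on the LAST underscore.

    Gene names may themselves contain underscores; allele names may not.
    A name without an underscore is a bare marker (no allele).
    """
    if not name:
        raise NamingError("empty target name")
    if "_" not in name:
        return MarkerSpec(marker=name, allele=None)
    marker, allele = name.rsplit("_", 1)
    if not marker:
        raise NamingError(f"target name {name!r} has an empty gene part")
    return MarkerSpec(marker=marker, allele=allele)


def render_target_name(spec: MarkerSpec) -> str:
    return spec.target_name


def well_marker_set(well: Well) -> frozenset[str]:
    return frozenset(parse_target_name(r.target_name).marker for r in well.reactions)


def _kit_id(markers: frozenset[str]) -> str:
    return "|".join(sorted(markers))


def infer_kits(experiment: Experiment, control_marker: str) -> list[KitSpec]:
    """Group wells by their marker set; each distinct set is one kit.

    The kit id is the sorted marker names joined with "|", so ids are stable
    across runs, well order and plates, and multi-file batches merge cleanly.
    A kit lacking the control marker is returned as-is (``has_control`` is
    False); the control check is a QC code, not a load failure.
    """
    marker_sets: set[frozenset[str]] = set()
    for plate in experiment.plates:
        for well in plate.wells:
            if well.reactions:
                marker_sets.add(well_marker_set(well))
    kits = [
        KitSpec(kit_id=_kit_id(ms), markers=ms, control_marker=control_marker)
        for ms in marker_sets
    ]
    kits.sort(key=lambda k: k.kit_id)
    return kits


class PairingOutcome:
    """Result of pairing a kit's wells on one plate.

    ``pairs`` holds resolved allele pairs; ``unpaired`` holds (sample_name,
    wells, reason) tuples for samples whose wells could not be paired —
    these feed kit_QC and produce NA genotype records downstream.
    """

    def __init__(self) -> None:
        self.pairs: list[WellPair] = []
        self.unpaired: list[tuple[str, list[Well], str]] = []


def _allele_signature(well: Well) -> frozenset[tuple[str, str]]:
    sig = set()
    for r in well.reactions:
        spec = parse_target_name(r.target_name)
        if spec.allele is not None:
            sig.add((spec.marker, spec.allele))
    return frozenset(sig)


def _build_pair(sample: str, kit: KitSpec, well_a: Well, well_b: Well,
                plate_id: str) -> WellPair | None:
    """Assemble the allele map of a candidate pair; None if not a valid pair.

    For each SNP marker the two wells must jointly carry exactly two distinct
    alleles (one per well); indel markers carry the same "+" target in both.
    """
    allele_map: dict[str, dict[str, str]] = defaultdict(dict)
    for well in (well_a, well_b):
        for r in well.reactions:
            spec = parse_target_name(r.target_name)
            if spec.allele is None:
                continue
            if spec.is_indel:
                allele_map[spec.marker]["+"] = "both"
                continue
            if spec.allele in allele_map[spec.marker]:
                return None  # same allele in both wells: duplicate, not a pair
            allele_map[spec.marker][spec.allele] = well.position
    for marker, amap in allele_map.items():
        if "+" in amap:
            continue
        if len(amap) != 2:
            return None
    return WellPair(sample_name=sample, kit=kit, well_a=well_a, well_b=well_b,
                    allele_map=dict(allele_map), plate_id=plate_id)


def pair_wells(plate: Plate, kit: KitSpec) -> PairingOutcome:
    """Pair a kit's wells by sample name within one plate.

    Exactly two wells of a sample form one pair. Replicates (equal sample
    names by convention) are accepted when the well count is even and wells
    split into two equal groups by allele layout; the groups are then zipped
    in position order into replicate pairs. Anything else is flagged
    unpaired.
    """
    outcome = PairingOutcome()
    by_sample: dict[str, list[Well]] = defaultdict(list)
    for well in plate.wells:
        if well.is_ntc:
            continue
        if well.reactions and well_marker_set(well) == kit.markers:
            by_sample[well.sample_name].append(well)

    for sample, wells in sorted(by_sample.items()):
        wells = sorted(wells, key=lambda w: w.position)
        if len(wells) == 2:
            pair = _build_pair(sample, kit, wells[0], wells[1], plate.plate_id)
            if pair is None:
                outcome.unpaired.append((sample, wells, "duplicate allele layout"))
            else:
                outcome.pairs.append(pair)
            continue
        if len(wells) % 2 == 0 and len(wells) > 2:
            groups: dict[frozenset, list[Well]] = defaultdict(list)
            for w in wells:
                groups[_allele_signature(w)].append(w)
            if len(groups) == 2:
                ga, gb = (sorted(g, key=lambda w: w.position) for g in groups.values())
                if len(ga) == len(gb):
                    pairs = [_build_pair(sample, kit, a, b, plate.plate_id)
                             for a, b in zip(ga, gb)]
                    if all(p is not None for p in pairs):
                        outcome.pairs.extend(pairs)
                        continue
            outcome.unpaired.append((sample, wells, "unpaired"))
            continue
        outcome.unpaired.append((sample, wells, "unpaired"))
    return outcome
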