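"""Core data model for multiplexed allele-specific qPCR analysis.

The unit of import is one instrument run file holding one or more plates.
Each well carries one reaction per detection channel; a reaction is a raw
amplification trace (cycle, fluorescence) annotated with a target name and
dye, optionally with the quantification cycle (Cq) already computed by the
instrument software.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AllelecallError",
    "LoadError",
    "SchemaError",
    "VersionError",
    "NamingError",
    "SettingsError",
    "DesignError",
    "Reaction",
    "Well",
    "Plate",
    "Experiment",
    "MarkerSpec",
    "KitSpec",
    "WellPair",
    "AnalysisSettings",
    "SigmoidFit",
    "CurveResult",
    "QCRecord",
    "GenotypeCall",
    "normalize_position",
]


class AllelecallError(Exception):
    """Base class for errors raised by this package."""


class LoadError(AllelecallError):
    """A data file could not be loaded."""


class SchemaError(AllelecallError):
    """A fixture file is missing a required column or field."""


class VersionError(LoadError):
    """The RDML document declares an unsupported major version."""


class NamingError(AllelecallError):
    """A target name violates the GENENAME_ALLELENAME convention."""


class SettingsError(AllelecallError):
    """Analysis settings are inconsistent with the data or with each other."""


class DesignError(AllelecallError):
    """A simulated panel design is internally inconsistent."""


_POSITION_RE = re.compile(r"^([A-Pa-p])0*(\d{1,2})$")


def normalize_position(position: str) -> str:
    """Normalize a well position to row letter + zero-padded 2-digit column.

    Instrument exports disagree on padding ("A1" vs "A01"); both are accepted.
    """
    m = _POSITION_RE.match(position.strip())
    if not m:
        raise SchemaError(f"invalid well position {position!r}")
    row, col = m.group(1).upper(), int(m.group(2))
    if not 1 <= col <= 24:
        raise SchemaError(f"well column out of range in {position!r}")
    return f"{row}{col:02d}"


@dataclass
class Reaction:
    """One amplification curve: a single (well, detection channel) readout."""

    target_name: str
    dye: str
    cycles: np.ndarray
    rfu: np.ndarray
    preprocessed_cq: float | None = None

    def __post_init__(self) -> None:
        self.cycles = np.asarray(self.cycles, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        if len(self.cycles) != len(self.rfu):
            raise SchemaError(
                f"reaction {self.target_name}: {len(self.cycles)} cycles "
                f"but {len(self.rfu)} fluorescence readings"
            )
        if len(self.cycles) >= 2 and not np.all(np.diff(self.cycles) > 0):
            raise SchemaError(f"reaction {self.target_name}: cycles not strictly increasing")


@dataclass
class Well:
    position: str
    sample_name: str
    sample_type: str = "unknown"  # "unknown" or "ntc"
    reactions: list[Reaction] = field(default_factory=list)

    @property
    def is_ntc(self) -> bool:
        return self.sample_type == "ntc"

    def reaction_for(self, target_name: str) -> Reaction | None:
        for r in self.reactions:
            if r.target_name == target_name:
                return r
        return None


@dataclass
class Plate:
    plate_id: str
    wells: list[Well] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        for w in self.wells:
            if w.position in seen:
                raise SchemaError(f"plate {self.plate_id}: duplicate well {w.position}")
            seen.add(w.position)


@dataclass
class Experiment:
    file_id: str
    plates: list[Plate] = field(default_factory=list)
    run_date: str | None = None

    def iter_reactions(self):
        for plate in self.plates:
            for well in plate.wells:
                for reaction in well.reactions:
                    yield plate, well, reaction

    @property
    def n_reactions(self) -> int:
        return sum(1 for _ in self.iter_reactions())


@dataclass(frozen=True)
class MarkerSpec:
    """A target name decomposed into marker (gene) and allele.

    ``allele`` is a nucleotide string, ``"+"`` for an indel presence/absence
    target, or ``None`` for a bare marker (e.g. the control gene).
    """

    marker: str
    allele: str | None

    @property
    def is_indel(self) -> bool:
        return self.allele == "+"

    @property
    def target_name(self) -> str:
        if self.allele is None:
            return self.marker
        return f"{self.marker}_{self.allele}"


@dataclass(frozen=True)
class KitSpec:
    """A primer-mix formulation: the set of markers co-occurring in wells."""

    kit_id: str
    markers: frozenset[str]
    control_marker: str

    @property
    def has_control(self) -> bool:
        return self.control_marker in self.markers


@dataclass
class WellPair:
    """Two wells of one sample in one kit, one per allele-specific mix."""

    sample_name: str
    kit: KitSpec
    well_a: Well
    well_b: Well
    # marker -> {allele: well position}; indel markers map {"+": both positions}
    allele_map: dict[str, dict[str, str]] = field(default_factory=dict)
    plate_id: str = ""


@dataclass
class AnalysisSettings:
    """User-tunable analysis parameters.

    Defaults mirror a typical AS-qPCR run on a 40-cycle protocol: Cq delta
    3.5 cycles, positive Cq window 15-25 cycles, endpoint threshold 200 RFU,
    baseline estimated over cycles 5-15.
    """

    control_marker: str | None = None
    cq_delta: float = 3.5
    cq_range: tuple[float, float] = (15.0, 25.0)
    rfu_threshold: float = 200.0
    preprocess: bool = True
    bg_range: tuple[int, int] = (5, 15)
    model_type: str = "b4"  # one of l4, l5, b4, b5
    cq_method: str = "cpD1"  # one of cpD1, cpD2, maxE, expR, Cy20
    weighted: bool = False

    def validate(self) -> None:
        if self.cq_range[0] >= self.cq_range[1]:
            raise SettingsError(f"cq_range low >= high: {self.cq_range}")
        if self.cq_delta <= 0:
            raise SettingsError("cq_delta must be positive")
        if self.rfu_threshold < 0:
            raise SettingsError("rfu_threshold must be non-negative")
        if self.bg_range[0] >= self.bg_range[1]:
            raise SettingsError(f"bg_range first >= last: {self.bg_range}")
        if self.model_type not in ("l4", "l5", "b4", "b5"):
            raise SettingsError(f"unknown model_type {self.model_type!r}")
        if self.cq_method not in ("cpD1", "cpD2", "maxE", "expR", "Cy20"):
            raise SettingsError(f"unknown cq_method {self.cq_method!r}")

    def as_dict(self) -> dict:
        return {
            "control_marker": self.control_marker,
            "cq_delta": self.cq_delta,
            "cq_range_low": self.cq_range[0],
            "cq_range_high": self.cq_range[1],
            "rfu_threshold": self.rfu_threshold,
            "preprocess": self.preprocess,
            "bg_range_first": self.bg_range[0],
            "bg_range_last": self.bg_range[1],
            "model_type": self.model_type,
            "cq_method": self.cq_method,
            "weighted": self.weighted,
        }


@dataclass
class SigmoidFit:
    """A fitted sigmoid amplification model.

    Parameters follow the standard 4/5-parameter log-logistic and logistic
    families: b slope, c lower asymptote, d upper asymptote, e inflection
    location, f asymmetry (five-parameter models only, fixed at 1 otherwise).
    """

    model_type: str
    b: float = float("nan")
    c: float = float("nan")
    d: float = float("nan")
    e: float = float("nan")
    f: float = 1.0
    rss: float = float("nan")
    converged: bool = False

    @property
    def amplitude(self) -> float:
        return abs(self.d - self.c)


@dataclass
class CurveResult:
    """Per-reaction derived values after (optional) preprocessing."""

    corrected_rfu: np.ndarray
    cycles: np.ndarray
    fit: SigmoidFit | None
    cq: float | None
    endpoint_rfu: float
    amp_status: str  # "ok" or "no_amp"


# QC code values
OK = "OK"
LOW = "Low"
NOAMP = "NoAmp"
FAIL = "Fail"


@dataclass
class QCRecord:
    """The per-reaction quality-control codes.

    Codes not applicable to a reaction stay "OK". ``kit_QC`` fails when the
    sample's wells for the kit cannot be paired on the plate.
    """

    plate_id: str
    position: str
    sample_name: str
    target_name: str
    RFU_QC: str = OK
    ampStatus_QC: str = OK
    replicateMatch_QC: str = OK
    noAmpNTC_QC: str = OK
    ctrlMarker_QC: str = OK
    allelesDeltaCq_QC: str = OK
    kit_QC: str = OK

    CODE_FIELDS = (
        "RFU_QC",
        "ampStatus_QC",
        "replicateMatch_QC",
        "noAmpNTC_QC",
        "ctrlMarker_QC",
        "allelesDeltaCq_QC",
        "kit_QC",
    )

    def as_dict(self) -> dict:
        d = {
            "plate": self.plate_id,
            "well": self.position,
            "sample": self.sample_name,
            "target": self.target_name,
        }
        for name in self.CODE_FIELDS:
            d[name] = getattr(self, name)
        return d


@dataclass
class GenotypeCall:
    """The genotype decision for one (sample, marker).

    ``call`` is an allele combination ("C/G", "C/C"), "Insertion",
    "Deletion", "Uncertain", or "NA". NA calls always carry reasons.
    """

    sample_name: str
    marker: str
    call: str
    reasons: list[str] = field(default_factory=list)
    cq_values: dict[str, float | None] = field(default_factory=dict)
    adjusted_delta: float | None = None
    plate_id: str = ""

    def __post_init__(self) -> None:
        if self.call == "NA" and not self.reasons:
            raise ValueError("NA call requires at least one reason")
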