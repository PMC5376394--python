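"""Individual covariates and organ-level physiology.

A whole-body perfusion-limited model needs, per subject, the volume of and
blood flow to every tissue compartment. This module turns an
:class:`Individual` (weight, sex, creatinine clearance, neutrophil count) into
:class:`OrganParameters` using a sex-specific :class:`PhysiologyTable` of body
weight fractions and cardiac-output fractions.

Scaling rules
-------------
* volumes: ``V_t = volume_fraction(sex, t) * weight / density_t``
* cardiac output: allometric, ``CO = CO_ref * (weight / ref_weight) ** 0.75``
  (exponent configurable)
* flows: ``Q_t = flow_fraction(sex, t) * CO`` for the parallel systemic
  tissues; the lung is in series and carries the full cardiac output.

The blood volume is split into arterial and venous pools with a configurable
arterial fraction (default 1:2 arterial:venous). The "rest" compartment lumps
all unnamed tissue so that volumes and flows close exactly: the shipped table
lists its fractions explicitly and validation enforces that the parallel flow
fractions sum to one and the volume fractions (tissues + blood) to at most
one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

from .config import default_physiology_config, load_yaml

__all__ = [
    "SEXES",
    "NAMED_TISSUES",
    "PARALLEL_TISSUES",
    "ALL_TISSUES",
    "Individual",
    "PhysiologyTable",
    "OrganParameters",
    "cardiac_output",
    "scale_physiology",
]

SEXES = ("male", "female")

#: The ten named tissues of the whole-body model. Lung is perfused in series
#: with the full cardiac output; the others sit in the parallel systemic
#: circuit together with the lumped "rest" compartment.
NAMED_TISSUES = (
    "lung", "brain", "heart", "skin", "muscle",
    "adipose", "spleen", "git", "liver", "kidney",
)
PARALLEL_TISSUES = NAMED_TISSUES[1:] + ("rest",)
ALL_TISSUES = NAMED_TISSUES + ("rest",)

_FLOW_TOL = 1e-9


@dataclass(frozen=True)
class Individual:
    """One virtual or real patient.

    Parameters
    ----------
    id : str
        Subject label.
    weight : float
        Total body weight, kg. Must be positive.
    sex : str
        ``"male"`` or ``"female"``.
    crcl : float
        Creatinine clearance, ml/min. Drives renal clearance.
    anc : float
        Absolute neutrophil count, cells/ul. Drives the immune-kill term;
        defaults to a normal-range 2500.
    """

    id: str
    weight: float
    sex: str
    crcl: float
    anc: float = 2500.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"weight must be positive, got {self.weight}")
        if self.sex not in SEXES:
            raise ValueError(f"sex must be one of {SEXES}, got {self.sex!r}")
        if self.crcl < 0:
            raise ValueError(f"crcl must be non-negative, got {self.crcl}")
        if self.anc < 0:
            raise ValueError(f"anc must be non-negative, got {self.anc}")


def _check_fraction(name: str, value: float) -> None:
    if not 0.0 < value < 1.0:
        raise ValueError(f"{name} must lie in (0, 1), got {value}")


@dataclass
class PhysiologyTable:
    """Sex-specific reference fractions for organ volumes and blood flows.

    ``volume_fractions`` and ``flow_fractions`` map tissue name to a
    ``{sex: fraction}`` mapping; ``volume_fractions`` additionally contains a
    ``"blood"`` entry. Validation is strict: unknown or missing tissues,
    fractions outside (0, 1), parallel flows not summing to one, or volume
    fractions summing above one all raise ``ValueError`` with the offending
    key in the message.
    """

    volume_fractions: dict[str, dict[str, float]]
    flow_fractions: dict[str, dict[str, float]]
    cardiac_output_ref: dict[str, float]
    ref_weight: dict[str, float]
    co_exponent: float = 0.75
    arterial_fraction: float = 1.0 / 3.0
    densities: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction ------------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: Mapping[str, Any]) -> "PhysiologyTable":
        """Build a table from a parsed config mapping (see shipped YAML)."""
        try:
            tissues = cfg["tissues"]
            blood = cfg["blood"]["volume_fraction"]
            ref = cfg["reference"]
        except KeyError as exc:
            raise ValueError(f"physiology config missing section {exc}") from exc
        vol = {t: dict(spec["volume_fraction"]) for t, spec in tissues.items()}
        flow = {t: dict(spec["flow_fraction"]) for t, spec in tissues.items()}
        vol["blood"] = dict(blood)
        return cls(
            volume_fractions=vol,
            flow_fractions=flow,
            cardiac_output_ref=dict(ref["cardiac_output_ref"]),
            ref_weight=dict(ref["ref_weight"]),
            co_exponent=float(ref.get("co_exponent", 0.75)),
            arterial_fraction=float(ref.get("arterial_fraction", 1.0 / 3.0)),
            densities={t: float(spec.get("density", 1.0)) for t, spec in tissues.items()},
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PhysiologyTable":
        return cls.from_dict(load_yaml(path))

    @classmethod
    def default(cls) -> "PhysiologyTable":
        """The packaged reference-man/-woman stand-in table."""
        return cls.from_dict(default_physiology_config())

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for t in ALL_TISSUES:
            if t not in self.volume_fractions:
                raise ValueError(f"physiology table missing volume fractions for {t!r}")
            if t not in self.flow_fractions:
                raise ValueError(f"physiology table missing flow fractions for {t!r}")
        if "blood" not in self.volume_fractions:
            raise ValueError("physiology table missing blood volume fraction")
        for sex in SEXES:
            for t, per_sex in self.volume_fractions.items():
                if sex not in per_sex:
                    raise ValueError(f"volume fraction for {t!r} missing sex {sex!r}")
                _check_fraction(f"volume_fraction[{t}][{sex}]", per_sex[sex])
            for t in PARALLEL_TISSUES:
                if sex not in self.flow_fractions[t]:
                    raise ValueError(f"flow fraction for {t!r} missing sex {sex!r}")
                _check_fraction(f"flow_fraction[{t}][{sex}]", self.flow_fractions[t][sex])
            flow_sum = sum(self.flow_fractions[t][sex] for t in PARALLEL_TISSUES)
            if abs(flow_sum - 1.0) > 1e-6:
                raise ValueError(
                    f"parallel flow fractions for sex {sex!r} sum to {flow_sum:.8f}, expected 1"
                )
            vol_sum = sum(self.volume_fractions[t][sex] for t in (*ALL_TISSUES, "blood"))
            if vol_sum > 1.0 + 1e-9:
                raise ValueError(
                    f"volume fractions for sex {sex!r} sum to {vol_sum:.8f} > 1"
                )
            if sex not in self.cardiac_output_ref or sex not in self.ref_weight:
                raise ValueError(f"reference cardiac output/weight missing sex {sex!r}")
        if not 0.0 < self.arterial_fraction < 1.0:
            raise ValueError("arterial_fraction must lie in (0, 1)")

    def density(self, tissue: str) -> float:
        return self.densities.get(tissue, 1.0)


@dataclass(frozen=True)
class OrganParameters:
    """Volumes (l) and blood flows (l/h) for one individual.

    ``volumes`` covers every tissue plus the ``arterial`` and ``venous``
    blood pools; ``flows`` covers the parallel tissues plus ``lung`` (which
    equals the cardiac output).
    """

    volumes: dict[str, float]
    flows: dict[str, float]
    cardiac_output: float

    def __post_init__(self) -> None:
        for name, v in self.volumes.items():
            if v <= 0:
                raise ValueError(f"volume of {name!r} must be positive, got {v}")
        for name, q in self.flows.items():
            if q <= 0:
                raise ValueError(f"flow to {name!r} must be positive, got {q}")
        parallel = sum(self.flows[t] for t in PARALLEL_TISSUES)
        if abs(parallel - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError(
                "parallel tissue flows do not conserve cardiac output: "
                f"{parallel} vs {self.cardiac_output}"
            )
        if abs(self.flows["lung"] - self.cardiac_output) > 1e-9 * self.cardiac_output:
            raise ValueError("lung flow must equal cardiac output")


def cardiac_output(individual: Individual, table: PhysiologyTable) -> float:
    """Allometrically scaled cardiac output, l/h."""
    ref_co = table.cardiac_output_ref[individual.sex]
    ref_w = table.ref_weight[individual.sex]
    return ref_co * (individual.weight / ref_w) ** table.co_exponent


def scale_physiology(individual: Individual, table: PhysiologyTable) -> OrganParameters:
    """Scale the reference table to one individual's weight and sex.

    Raises
    ------
    ValueError
        If the individual's sex is absent from the table (guarded by
        :class:`Individual` for the standard sexes) or the weight is invalid.
    """
    sex = individual.sex
    if sex not in table.cardiac_output_ref:
        raise ValueError(f"sex {sex!r} not present in physiology table")
    w = individual.weight
    co = cardiac_output(individual, table)

    volumes: dict[str, float] = {}
    for t in ALL_TISSUES:
        volumes[t] = table.volume_fractions[t][sex] * w / table.density(t)
    blood = table.volume_fractions["blood"][sex] * w / table.density("blood")
    volumes["arterial"] = table.arterial_fraction * blood
    volumes["venous"] = (1.0 - table.arterial_fraction) * blood

    flows = {t: table.flow_fractions[t][sex] * co for t in PARALLEL_TISSUES}
    # remove rounding drift so the parallel circuit conserves CO exactly
    drift = co - sum(flows.values())
    flows["rest"] += drift
    flows["lung"] = co
    return OrganParameters(volumes=volumes, flows=flows, cardiac_output=co)
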