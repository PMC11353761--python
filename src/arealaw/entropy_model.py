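"""Area-law entropy models and the ultraviolet-cutoff coefficient.

The central model predicts gas-phase standard entropy (J/mol·K) from the
surface descriptor of a molecule:

    S_tharea = S0 + a·A_spherical + b·Σ p⁺ ln p⁺ · A  + c·Σ p⁻ ln p⁻ · A

The spherical area enters with weight ``a`` (entropy per Å² of free,
undeformed atomic surface); the deformation aggregates are non-positive,
so with b, c > 0 bonds always *reduce* the predicted entropy.  Two nested
baselines — entropy proportional to total surface area or to molecular
volume — are provided for comparison.

Packaged default coefficients are the published calibration against 1942
experimental gas-phase entropies, stored with their 95% bootstrap
confidence bounds in a versioned JSON asset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .shapestats import SurfaceDescriptor

__all__ = [
    "EntropyCoefficients",
    "AVOGADRO",
    "BOLTZMANN",
    "load_default_coefficients",
    "predict_stharea",
    "predict_sarea",
    "predict_svolume",
    "uv_cutoff_coefficient",
]

#: CODATA 2018 exact values
AVOGADRO = 6.02214076e23  # mol^-1
BOLTZMANN = 1.380649e-23  # J/K

_MODEL_TAGS = ("area_deformation", "area_only", "volume_only")


@dataclass
class EntropyCoefficients:
    """(S0, a, b, c) in J/mol·K (S0) and J/mol·K per Å² (a, b, c).

    For the volume-only model the slope is stored in ``a`` with units
    J/mol·K per Å³.  ``ci`` optionally carries per-parameter 95% bootstrap
    bounds, ``meta`` the geometry settings the fit is valid for.
    """

    model_tag: str
    s0: float
    a: float
    b: float = 0.0
    c: float = 0.0
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.model_tag not in _MODEL_TAGS:
            raise ValueError(f"model_tag must be one of {_MODEL_TAGS}, got {self.model_tag!r}")

    def as_dict(self) -> dict:
        return {
            "model_tag": self.model_tag,
            "s0": self.s0,
            "a": self.a,
            "b": self.b,
            "c": self.c,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "meta": self.meta,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, payload: dict) -> "EntropyCoefficients":
        return cls(
            model_tag=payload["model_tag"],
            s0=float(payload["s0"]),
            a=float(payload["a"]),
            b=float(payload.get("b", 0.0)),
            c=float(payload.get("c", 0.0)),
            ci={k: (float(v[0]), float(v[1])) for k, v in payload.get("ci", {}).items()},
            meta=payload.get("meta", {}),
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "EntropyCoefficients":
        return cls.from_dict(json.loads(Path(path).read_text()))


def load_default_coefficients(model_tag: str = "area_deformation") -> EntropyCoefficients:
    """Packaged published coefficients (no volume-only set was published)."""
    ref = resources.files("arealaw").joinpath("data/coefficients.json")
    payload = json.loads(ref.read_text())
    if model_tag not in payload:
        raise KeyError(
            f"no packaged coefficients for {model_tag!r}; available: {sorted(payload)}"
        )
    coeffs = EntropyCoefficients.from_dict(payload[model_tag])
    if coeffs.model_tag in ("area_deformation",) and not (coeffs.b > 0 and coeffs.c > 0):
        raise ValueError("packaged deformation coefficients must have b > 0 and c > 0")
    return coeffs


def predict_stharea(desc: SurfaceDescriptor, coeffs: EntropyCoefficients) -> float:
    """Area-law entropy with deformation corrections, J/mol·K."""
    if coeffs.model_tag != "area_deformation":
        raise ValueError(f"expected area_deformation coefficients, got {coeffs.model_tag}")
    return float(
        coeffs.s0
        + coeffs.a * desc.area_spherical
        + coeffs.b * desc.sum_pos
        + coeffs.c * desc.sum_neg
    )


def predict_sarea(total_area: float, coeffs: EntropyCoefficients) -> float:
    """Area-only baseline S = S0 + a·A, J/mol·K."""
    if coeffs.model_tag != "area_only":
        raise ValueError(f"expected area_only coefficients, got {coeffs.model_tag}")
    return float(coeffs.s0 + coeffs.a * total_area)


def predict_svolume(total_volume: float, coeffs: EntropyCoefficients) -> float:
    """Volume-only baseline S = S0 + v·V (slope stored in ``a``), J/mol·K."""
    if coeffs.model_tag != "volume_only":
        raise ValueError(f"expected volume_only coefficients, got {coeffs.model_tag}")
    return float(coeffs.s0 + coeffs.a * total_volume)


def uv_cutoff_coefficient(
    a_coefficient: float,
    l_uv: float = 1.1,
    avogadro: float = AVOGADRO,
    boltzmann: float = BOLTZMANN,
) -> float:
    """Dimensionless ultraviolet-cutoff coefficient C_UV = a·L_UV² / (N_A·k_B).

    ``a_coefficient`` is the area slope in J/mol·K·Å⁻² and ``l_uv`` the
    cutoff length in Å (default: the 1.1 Å hydrogen van der Waals radius).
    The analogous constants are 1/4 for black-hole entropy and 0.30 for
    coupled harmonic oscillators.
    """
    if a_coefficient < 0 or l_uv <= 0 or avogadro <= 0 or boltzmann <= 0:
        raise ValueError("all inputs must be positive (a_coefficient may be 0)")
    return float(a_coefficient * l_uv**2 / (avogadro * boltzmann))
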