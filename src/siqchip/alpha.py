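"""Normalization constant alpha for quantitative (siQ) ChIP-seq.

In siQ-ChIP the ratio of IP to input read counts on a genomic interval is
placed on a physical capture-efficiency scale by a single proportionality
constant, alpha. Alpha is a product of material-tracking ratios measured at
the bench for both the IP and the input sample:

* ``rho`` -- bead-capture yield of the sequencing library (captured /
  expected library concentration); absorbs losses during library cleanup
  and, partially, deviations from perfect PCR doubling.
* ``F_L`` -- fraction of the final library molar amount that was actually
  loaded on the sequencer.
* ``2^c`` -- PCR amplification with ``c`` cycles.
* ``F``  -- fraction of the immunoprecipitated DNA mass carried into
  library preparation.
* the reaction volume factor ``v_in / (V - v_in)``, relating the input
  aliquot volume to the IP volume.

Scaling the observed mapped-read count R-hat up by every known loss gives
the number of fragments the *whole* IP material would have produced,

    R = R_hat / (F_L * 2**c * rho * F)

and alpha is the ratio of the input-sample factors to the IP-sample
factors, with the volume factor folded in:

    alpha = (rho_in/rho) * (F_L,in/F_L) * (F_in/F) * v_in/(V - v_in)

All of these quantities are dimensionless ratios; manifests therefore
carry unit *tags* (fmol, ng, ul) and a ratio mixing units is rejected
rather than silently converted.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ManifestError",
    "SampleManifest",
    "ReactionVolumes",
    "AlphaResult",
    "fraction_sequenced",
    "fraction_into_library",
    "scaled_total_reads",
    "compute_alpha",
    "alpha_ratio",
    "load_manifest",
    "dump_manifest",
    "format_report",
]


class ManifestError(ValueError):
    """An experiment manifest violates its physical invariants."""


_QUANTITY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([A-Za-zμ]*)\s*$")


def _parse_quantity(raw, expected_unit: str, name: str) -> float:
    """Parse ``raw`` (number, or string like ``"20 fmol"``) into a float.

    A unit tag, when present, must match ``expected_unit`` exactly;
    mismatches raise rather than convert.
    """
    if isinstance(raw, (int, float)):
        return float(raw)
    m = _QUANTITY_RE.match(str(raw))
    if not m:
        raise ManifestError(f"{name}: cannot parse quantity {raw!r}")
    value, unit = float(m.group(1)), m.group(2)
    if unit and unit != expected_unit:
        raise ManifestError(
            f"{name}: unit {unit!r} does not match expected {expected_unit!r}; "
            "convert at the bench, not in the manifest"
        )
    return value


def _ratio(numerator: float, denominator: float, what: str) -> float:
    if not (numerator > 0 and denominator > 0):
        raise ManifestError(f"{what}: amounts must be positive, got "
                            f"{numerator} / {denominator}")
    if numerator > denominator:
        raise ManifestError(f"{what}: part {numerator} exceeds whole {denominator}")
    return numerator / denominator


def fraction_sequenced(sequenced: float, total: float) -> float:
    """Fraction F_L of the library molar amount that was sequenced.

    Both amounts must be in the same molar unit (fmol by convention).
    """
    return _ratio(sequenced, total, "fraction_sequenced")


def fraction_into_library(mass_used: float, mass_total: float) -> float:
    """Fraction F of recovered IP (or input) DNA mass carried into library prep."""
    return _ratio(mass_used, mass_total, "fraction_into_library")


@dataclass
class SampleManifest:
    """Bench measurements for one sample (IP or input) that enter alpha.

    Parameters
    ----------
    mapped_reads
        R-hat, total mapped fragments actually sequenced.
    library_sequenced, library_total
        Molar amounts (fmol) of library loaded on the sequencer and of the
        whole library; their ratio is F_L.
    pcr_cycles
        c, library amplification cycles.
    ip_mass_total, mass_into_library
        DNA mass (ng) recovered from the IP (or input aliquot) and the part
        carried into library prep; their ratio is F.
    bead_capture_yield
        rho, captured over expected library concentration after bead
        cleanup. Values above 1 are accepted (they absorb global deviations
        from perfect 2**c amplification). Defaults to 1 (no-loss limit)
        with a logged warning when not measured.
    """

    mapped_reads: float
    library_sequenced: float
    library_total: float
    pcr_cycles: int
    ip_mass_total: float
    mass_into_library: float
    bead_capture_yield: float = 1.0
    name: str = ""

    def __post_init__(self) -> None:
        if self.mapped_reads <= 0:
            raise ManifestError(f"{self.name or 'sample'}: mapped_reads must be > 0")
        if self.pcr_cycles < 0:
            raise ManifestError(f"{self.name or 'sample'}: pcr_cycles must be >= 0")
        if self.bead_capture_yield <= 0:
            raise ManifestError(
                f"{self.name or 'sample'}: bead_capture_yield (rho) must be > 0"
            )
        # ratio validity (positivity, part <= whole) checked eagerly
        self.fraction_sequenced
        self.fraction_into_library

    @property
    def fraction_sequenced(self) -> float:
        """F_L = library_sequenced / library_total."""
        return fraction_sequenced(self.library_sequenced, self.library_total)

    @property
    def fraction_into_library(self) -> float:
        """F = mass_into_library / ip_mass_total."""
        return fraction_into_library(self.mass_into_library, self.ip_mass_total)

    @classmethod
    def from_dict(cls, data: dict, name: str = "") -> "SampleManifest":
        d = dict(data)
        if "bead_capture_yield" not in d or d["bead_capture_yield"] is None:
            logger.warning(
                "%s: bead_capture_yield (rho) not measured; defaulting to 1 "
                "(no-loss limit)", name or "sample")
            d["bead_capture_yield"] = 1.0
        try:
            return cls(
                mapped_reads=_parse_quantity(d["mapped_reads"], "", "mapped_reads"),
                library_sequenced=_parse_quantity(
                    d["library_sequenced"], "fmol", "library_sequenced"),
                library_total=_parse_quantity(
                    d["library_total"], "fmol", "library_total"),
                pcr_cycles=int(d["pcr_cycles"]),
                ip_mass_total=_parse_quantity(
                    d["ip_mass_total"], "ng", "ip_mass_total"),
                mass_into_library=_parse_quantity(
                    d["mass_into_library"], "ng", "mass_into_library"),
                bead_capture_yield=_parse_quantity(
                    d["bead_capture_yield"], "", "bead_capture_yield"),
                name=name,
            )
        except KeyError as exc:  # pragma: no cover - trivial message path
            raise ManifestError(f"{name or 'sample'}: missing field {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "mapped_reads": self.mapped_reads,
            "library_sequenced": self.library_sequenced,
            "library_total": self.library_total,
            "pcr_cycles": self.pcr_cycles,
            "ip_mass_total": self.ip_mass_total,
            "mass_into_library": self.mass_into_library,
            "bead_capture_yield": self.bead_capture_yield,
        }


@dataclass
class ReactionVolumes:
    """IP reaction volume V and the input aliquot v_in removed from it (ul)."""

    total_volume: float
    input_aliquot: float

    def __post_init__(self) -> None:
        if not (0 < self.input_aliquot < self.total_volume):
            raise ManifestError(
                "volumes: need 0 < input_aliquot < total_volume, got "
                f"v_in={self.input_aliquot}, V={self.total_volume}")

    @property
    def volume_factor(self) -> float:
        """v_in / (V - v_in), the factor folded into alpha."""
        return self.input_aliquot / (self.total_volume - self.input_aliquot)

    @classmethod
    def from_dict(cls, data: dict) -> "ReactionVolumes":
        return cls(
            total_volume=_parse_quantity(data["total_volume"], "ul", "total_volume"),
            input_aliquot=_parse_quantity(data["input_aliquot"], "ul", "input_aliquot"),
        )

    def to_dict(self) -> dict:
        return {"total_volume": self.total_volume, "input_aliquot": self.input_aliquot}


@dataclass
class AlphaResult:
    """Alpha together with every intermediate factor, for reporting.

    ``factors`` holds the four constituents of alpha (rho ratio, library
    fraction ratio, mass fraction ratio, volume factor); all of them should
    be reported alongside alpha so that experiments can be compared
    factor by factor.
    """

    alpha: float
    ip_scaled_reads: float
    input_scaled_reads: float
    factors: dict = field(default_factory=dict)

    @property
    def alpha_inverse(self) -> float:
        return 1.0 / self.alpha


def scaled_total_reads(manifest: SampleManifest) -> float:
    """Fragments obtainable by sequencing *all* material of this sample.

    R = R_hat / (F_L * 2**c * rho * F): the observed mapped-read count
    scaled up by every known source of loss and down-sampling. Returned at
    full precision (not rounded to an integer count).
    """
    f_l = manifest.fraction_sequenced
    f = manifest.fraction_into_library
    rho = manifest.bead_capture_yield
    for value, label in ((rho, "bead_capture_yield (rho)"),
                         (f, "mass fraction into library (F)"),
                         (f_l, "library fraction sequenced (F_L)")):
        if value == 0:
            raise ManifestError(f"cannot scale reads: {label} is zero")
    return manifest.mapped_reads / (f_l * 2.0 ** manifest.pcr_cycles * rho * f)


def compute_alpha(ip: SampleManifest, input: SampleManifest,
                  volumes: ReactionVolumes) -> AlphaResult:
    """Compute alpha = (rho_in/rho)(F_L,in/F_L)(F_in/F) * v_in/(V - v_in).

    The volume factor is included in alpha but also reported separately in
    ``factors`` so users comparing against the bare factor-ratio definition
    can reconcile the two conventions.
    """
    factors = {
        "rho_ratio": input.bead_capture_yield / ip.bead_capture_yield,
        "library_fraction_ratio": input.fraction_sequenced / ip.fraction_sequenced,
        "mass_fraction_ratio": input.fraction_into_library / ip.fraction_into_library,
        "volume_factor": volumes.volume_factor,
        "ip": {
            "F_L": ip.fraction_sequenced,
            "F": ip.fraction_into_library,
            "rho": ip.bead_capture_yield,
            "pcr_cycles": ip.pcr_cycles,
        },
        "input": {
            "F_L": input.fraction_sequenced,
            "F": input.fraction_into_library,
            "rho": input.bead_capture_yield,
            "pcr_cycles": input.pcr_cycles,
        },
    }
    alpha = (factors["rho_ratio"] * factors["library_fraction_ratio"]
             * factors["mass_fraction_ratio"] * factors["volume_factor"])
    result = AlphaResult(
        alpha=alpha,
        ip_scaled_reads=scaled_total_reads(ip),
        input_scaled_reads=scaled_total_reads(input),
        factors=factors,
    )
    logger.info("alpha = %.6g (1/alpha = %.6g); factors: rho %.4g, F_L %.4g, "
                "F %.4g, volume %.4g", alpha, 1 / alpha, factors["rho_ratio"],
                factors["library_fraction_ratio"], factors["mass_fraction_ratio"],
                factors["volume_factor"])
    return result


def alpha_ratio(a: AlphaResult, b: AlphaResult) -> dict:
    """Ratio of alpha scales between two conditions.

    The ratio of alphas between two experiments equals the material
    difference between the samples as they arrive at the sequencer. Both
    the direct ratio alpha_a/alpha_b and the inverse-alpha ratio
    (1/alpha_b)/(1/alpha_a are reciprocal views; printed factor tables in
    the field use either) are returned so no guess is made about which
    convention a reader expects.
    """
    if not (a.alpha > 0 and b.alpha > 0):
        raise ManifestError("alpha_ratio requires positive alphas")
    return {
        "alpha_ratio": a.alpha / b.alpha,
        "inverse_alpha_ratio": a.alpha_inverse / b.alpha_inverse,
    }


def load_manifest(path) -> tuple[SampleManifest, SampleManifest, ReactionVolumes]:
    """Read an experiment manifest (YAML with ``ip:``, ``input:``, ``volumes:``)."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ManifestError(f"{path}: manifest must be a mapping")
    for key in ("ip", "input", "volumes"):
        if key not in data:
            raise ManifestError(f"{path}: missing '{key}' block")
    ip = SampleManifest.from_dict(data["ip"], name="ip")
    inp = SampleManifest.from_dict(data["input"], name="input")
    volumes = ReactionVolumes.from_dict(data["volumes"])
    return ip, inp, volumes


def dump_manifest(ip: SampleManifest, input: SampleManifest,
                  volumes: ReactionVolumes, path) -> None:
    """Write a manifest that :func:`load_manifest` reads back bit-identically."""
    data = {"ip": ip.to_dict(), "input": input.to_dict(),
            "volumes": volumes.to_dict()}
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=True)


def _sig4(x: float) -> str:
    if x == 0 or not math.isfinite(x):
        return str(x)
    return f"{x:.4g}"


def format_report(result: AlphaResult) -> str:
    """Human-readable factor report; 4 significant figures throughout."""
    f = result.factors
    lines = [
        "siQ-ChIP alpha report",
        f"  alpha                 = {_sig4(result.alpha)}",
        f"  1/alpha               = {_sig4(result.alpha_inverse)}",
        f"  rho_in/rho            = {_sig4(f['rho_ratio'])}",
        f"  F_L,in/F_L            = {_sig4(f['library_fraction_ratio'])}",
        f"  F_in/F                = {_sig4(f['mass_fraction_ratio'])}",
        f"  v_in/(V - v_in)       = {_sig4(f['volume_factor'])}",
        f"  IP:    F_L = {_sig4(f['ip']['F_L'])}  F = {_sig4(f['ip']['F'])}"
        f"  rho = {_sig4(f['ip']['rho'])}  c = {f['ip']['pcr_cycles']}",
        f"  input: F_L = {_sig4(f['input']['F_L'])}  F = {_sig4(f['input']['F'])}"
        f"  rho = {_sig4(f['input']['rho'])}  c = {f['input']['pcr_cycles']}",
        f"  IP scaled reads R     = {_sig4(result.ip_scaled_reads)}",
        f"  input scaled reads R  = {_sig4(result.input_scaled_reads)}",
    ]
    return "\n".join(lines)
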