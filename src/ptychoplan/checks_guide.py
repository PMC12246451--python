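"""Feasibility checks and the camera-length guide.

The rules engine evaluates a plan's :class:`~ptychoplan.sampling.SamplingReport`
against the built-in acquisition limits.  For iterative methods (ITR):
detector coverage between 1α and a configurable low-count ceiling (6α),
probe overlap ≥ 70 %, maximum detected angle within the small-angle
regime (10°), resolution gain ≥ 1, combined sampling Ŝ ≥ 1, pattern
recovery level ≤ Ŝ, and the probe fitting half the probe window.  For the
direct SSB method: scan step within the λ/(2 sin 2α) bound, plus two
fixed limits — detector coverage ≥ 1α and a bright-field disk of at least
4 pixels.

Verdicts are three-state: fixed limits fail hard; editable limits warn
when the measured value is within 10 % of the threshold.  The guide
re-evaluates everything across a ladder of camera lengths, reproducing
the design tool's camera-length selection table.
"""

from __future__ import annotations

import dataclasses
import enum
import json
import math
from dataclasses import dataclass, replace

from .instrument import AcquisitionPlan, Method, derive_geometry
from .sampling import SamplingReport, build_report

__all__ = [
    "Verdict",
    "CheckSpec",
    "CheckResult",
    "CheckReport",
    "GuideRow",
    "default_checks",
    "run_checks",
    "camera_length_guide",
    "ssb_max_camera_length",
]

_WARN_BAND = 0.10  # editable checks warn within 10 % of their threshold


class Verdict(str, enum.Enum):
    PASS = "pass"
    WARN = "warn"
    FAIL = "fail"


@dataclass(frozen=True)
class CheckSpec:
    """One feasibility rule: a bound on a report quantity.

    ``bound`` is "ge" (measured ≥ threshold) or "le" (measured ≤
    threshold).  ``fixed`` rules have no warning band and may not be
    edited without acknowledging the method's hard limits.
    """

    id: str
    description: str
    applicability: Method
    quantity: str
    bound: str
    threshold: float
    fixed: bool = False

    def __post_init__(self) -> None:
        if self.bound not in ("ge", "le"):
            raise ValueError("bound must be 'ge' or 'le'")


def default_checks(
    low_count_alpha: float = 6.0, pattern_recovery_level: float = 1.0
) -> tuple[CheckSpec, ...]:
    """The built-in rule set with its default thresholds."""
    return (
        CheckSpec(
            "itr_coverage_min",
            "Detector covers at least the BF disk (>= 1α)",
            Method.ITR, "coverage_alpha", "ge", 1.0,
        ),
        CheckSpec(
            "itr_coverage_max",
            "Detector coverage stays below the low-count area",
            Method.ITR, "coverage_alpha", "le", low_count_alpha,
        ),
        CheckSpec(
            "itr_probe_overlap",
            "Significant real-space probe overlap",
            Method.ITR, "overlap_pct", "ge", 70.0,
        ),
        CheckSpec(
            "itr_small_angle",
            "Maximum detected angle within the small-angle regime",
            Method.ITR, "theta_mrad", "le", math.radians(10.0) * 1e3,
        ),
        CheckSpec(
            "itr_resolution_gain",
            "Reconstructed image has more pixels than scan positions",
            Method.ITR, "resolution_gain", "ge", 1.0,
        ),
        CheckSpec(
            "itr_combined_sampling",
            "Combined real- and reciprocal-space sampling Ŝ >= 1",
            Method.ITR, "s_hat", "ge", 1.0,
        ),
        CheckSpec(
            "itr_pattern_recovery",
            "Chosen pattern recovery level is below the combined sampling",
            Method.ITR, "pattern_recovery_margin", "ge", pattern_recovery_level,
        ),
        CheckSpec(
            "itr_probe_window",
            "Probe fits half the probe window (Nyquist condition)",
            Method.ITR, "probe_window_margin", "ge", 0.0,
        ),
        CheckSpec(
            "ssb_step",
            "Scan step within the semi-angle related sampling bound",
            Method.SSB, "step_margin_A", "ge", 0.0,
        ),
        CheckSpec(
            "ssb_coverage",
            "Detector covers at least the BF disk (>= 1α)",
            Method.SSB, "coverage_alpha", "ge", 1.0, fixed=True,
        ),
        CheckSpec(
            "ssb_min_bf_disk",
            "BF disk diameter at least 4 detector pixels",
            Method.SSB, "bf_disk_px", "ge", 4.0, fixed=True,
        ),
    )


@dataclass(frozen=True)
class CheckResult:
    id: str
    description: str
    measured: float
    threshold: float
    bound: str
    verdict: Verdict
    message: str


@dataclass(frozen=True)
class CheckReport:
    method: Method
    results: tuple[CheckResult, ...]
    overall: Verdict

    def to_json(self) -> str:
        """Deterministic JSON rendering (same input → same bytes)."""
        payload = {
            "method": self.method.value,
            "overall": self.overall.value,
            "checks": [
                {**dataclasses.asdict(r), "verdict": r.verdict.value}
                for r in self.results
            ],
        }
        return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _measured_quantities(report: SamplingReport) -> dict[str, float]:
    # Derived margins turn two-sided comparisons into simple ge-bounds.
    return {
        "coverage_alpha": report.coverage_alpha,
        "overlap_pct": report.overlap_pct,
        "theta_mrad": report.theta_mrad,
        "resolution_gain": report.resolution_gain,
        "s_hat": report.s_hat,
        "pattern_recovery_margin": report.s_hat,
        "probe_window_margin": report.d_probe_max_A - report.d_probe_A,
        "step_margin_A": report.ssb_max_step_A - report.step_used_A,
        "bf_disk_px": report.bf_disk_px,
    }


def _evaluate(spec: CheckSpec, measured: float) -> CheckResult:
    if spec.bound == "ge":
        ok = measured >= spec.threshold
        margin = measured - spec.threshold
    else:
        ok = measured <= spec.threshold
        margin = spec.threshold - measured
    if not ok:
        verdict = Verdict.FAIL
    elif spec.fixed:
        verdict = Verdict.PASS
    else:
        scale = max(abs(spec.threshold), 1e-12)
        verdict = Verdict.WARN if margin <= _WARN_BAND * scale else Verdict.PASS
    op = ">=" if spec.bound == "ge" else "<="
    message = f"{spec.quantity} = {measured:.6g} (required {op} {spec.threshold:.6g})"
    return CheckResult(
        id=spec.id,
        description=spec.description,
        measured=measured,
        threshold=spec.threshold,
        bound=spec.bound,
        verdict=verdict,
        message=message,
    )


def run_checks(
    plan: AcquisitionPlan,
    report: SamplingReport | None = None,
    specs: tuple[CheckSpec, ...] | None = None,
) -> CheckReport:
    """Evaluate the rule set applicable to the plan's method.

    Overall verdict: fail if any rule fails, else warn if any rule warns,
    else pass.
    """
    if report is None:
        report = build_report(plan)
    if specs is None:
        specs = default_checks()
    quantities = _measured_quantities(report)
    results = []
    for spec in specs:
        if spec.applicability != plan.method:
            continue
        if spec.quantity not in quantities:
            raise KeyError(f"check {spec.id!r} needs unknown quantity {spec.quantity!r}")
        results.append(_evaluate(spec, quantities[spec.quantity]))
    if any(r.verdict is Verdict.FAIL for r in results):
        overall = Verdict.FAIL
    elif any(r.verdict is Verdict.WARN for r in results):
        overall = Verdict.WARN
    else:
        overall = Verdict.PASS
    return CheckReport(method=plan.method, results=tuple(results), overall=overall)


@dataclass(frozen=True)
class GuideRow:
    """One camera-length row of the guide table."""

    nominal_camera_length_cm: float
    effective_camera_length_cm: float
    dtheta_mrad: float
    theta_mrad: float
    coverage_alpha: float
    itr_pixel_A: float
    depth_resolution_A: float
    probe_window_A: float
    d_probe_max_A: float
    s_hat: float
    overall_verdict: Verdict


def camera_length_guide(
    plan: AcquisitionPlan,
    camera_lengths_cm: list[float] | list[tuple[float, float]],
    specs: tuple[CheckSpec, ...] | None = None,
) -> list[GuideRow]:
    """Re-evaluate the plan across a ladder of camera lengths.

    Entries may be effective lengths (floats) or (nominal, effective)
    pairs from a calibration table.  One row per length, carrying the key
    sampling figures and the overall check verdict.
    """
    if not camera_lengths_cm:
        raise ValueError("camera length list must not be empty")
    rows = []
    for entry in camera_lengths_cm:
        nominal, effective = (
            entry if isinstance(entry, tuple) else (entry, entry)
        )
        p = replace(plan, detector=replace(plan.detector, camera_length_cm=effective))
        report = build_report(p)
        verdict = run_checks(p, report, specs).overall
        rows.append(
            GuideRow(
                nominal_camera_length_cm=nominal,
                effective_camera_length_cm=effective,
                dtheta_mrad=report.dtheta_mrad,
                theta_mrad=report.theta_mrad,
                coverage_alpha=report.coverage_alpha,
                itr_pixel_A=report.itr_pixel_A,
                depth_resolution_A=report.depth_resolution_A,
                probe_window_A=report.probe_window_A,
                d_probe_max_A=report.d_probe_max_A,
                s_hat=report.s_hat,
                overall_verdict=verdict,
            )
        )
    return rows


def ssb_max_camera_length(
    plan: AcquisitionPlan, camera_lengths_cm: list[float] | list[tuple[float, float]]
) -> float | None:
    """Largest camera length still placing at least 1α on the detector.

    Longer camera lengths magnify the pattern; beyond this value the BF
    disk no longer fits.  Returns the effective length, or None if no
    candidate qualifies.
    """
    if not camera_lengths_cm:
        raise ValueError("camera length list must not be empty")
    best = None
    for entry in camera_lengths_cm:
        _, effective = entry if isinstance(entry, tuple) else (entry, entry)
        p = replace(plan, detector=replace(plan.detector, camera_length_cm=effective))
        geo = derive_geometry(p)
        if geo.coverage_alpha >= 1.0 and (best is None or effective > best):
            best = effective
    return best
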