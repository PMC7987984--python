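"""Recompute headline quantities from the bundled NFHS-4 reference estimates.

Each check evaluates a bundled fitted curve with the package's own code —
summing it over integer ages for an implied TFR, or maximising it over the
age range for the peak — and compares the result with the corresponding
published value.  Everything here is deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import families, nfhs4, selection

__all__ = ["Check", "headline_checks"]


@dataclass(frozen=True)
class Check:
    name: str
    value: float
    published: float
    tol: float

    @property
    def passed(self) -> bool:
        return abs(self.value - self.published) <= self.tol


def headline_checks() -> list[Check]:
    """The deterministic reference checks, in a fixed order."""
    checks: list[Check] = []

    for region in ("India", "Uttar Pradesh", "Gujarat"):
        tfr = families.model_implied_tfr(
            "modified_gompertz", nfhs4.MODIFIED_GOMPERTZ_ESTIMATES[region])
        checks.append(Check(
            name=f"modified_gompertz_implied_tfr_{region.lower().replace(' ', '_')}",
            value=tfr, published=nfhs4.OBSERVED_TFR[region], tol=0.05))

    peak_age, peak_rate = families.model_peak(
        "modified_gompertz", nfhs4.MODIFIED_GOMPERTZ_ESTIMATES["India"])
    pub_rate, pub_age = nfhs4.OBSERVED_PEAK["India"]
    checks.append(Check("modified_gompertz_peak_rate_india",
                        peak_rate, pub_rate, 0.005))
    checks.append(Check("modified_gompertz_peak_age_india",
                        float(round(peak_age)), float(pub_age), 0.0))

    wb_age, _ = families.model_peak(
        "modified_pk", nfhs4.MODIFIED_PK_ESTIMATES["West Bengal"])
    checks.append(Check("modified_pk_peak_age_west_bengal",
                        float(round(wb_age)),
                        float(nfhs4.OBSERVED_PEAK["West Bengal"][1]), 0.0))

    a = [nfhs4.HADWIGER_ESTIMATES[r]["a"] for r in nfhs4.REGIONS]
    tfrs = [nfhs4.OBSERVED_TFR[r] for r in nfhs4.REGIONS]
    checks.append(Check("hadwiger_a_tfr_correlation",
                        round(selection.correlate_params(a, tfrs), 3),
                        nfhs4.HADWIGER_A_TFR_CORRELATION, 0.0005))
    return checks
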