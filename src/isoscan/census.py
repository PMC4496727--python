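"""Closed-form estimator of the total number of coding transcripts.

The estimator assumes the predictor's sensitivity measured on the known
transcript set carries over to transcripts not yet discovered.  With

* ``I_plus_II`` — predictions consistent with the known annotation (whether
  or not additionally validated by expression data),
* ``III`` — expected true novel validated transcripts (the validated-novel
  count deflated by the experimentally estimated precision),
* ``IV`` — true novel transcripts among the unvalidated predictions
  (0 in lower-bound mode),
* ``known_total`` — the size of the known transcript set,

the sensitivity is ``Sn = I_plus_II / known_total`` and the estimated total
is ``(I_plus_II + III + IV) / Sn``.  With ``III = IV = 0`` the estimate
reduces to ``known_total`` exactly.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class CensusInputs:
    I_plus_II: int
    III: int
    IV: int
    known_total: int

    def __post_init__(self) -> None:
        if min(self.I_plus_II, self.III, self.IV, self.known_total) < 0:
            raise ValueError("census counts must be non-negative")
        if self.I_plus_II > self.known_total:
            raise ValueError("I + II cannot exceed the known-set size")


def sensitivity_known(inputs: CensusInputs) -> float:
    """Predictor sensitivity on the known transcript set."""
    if inputs.known_total == 0:
        raise ValueError("known_total must be positive")
    return inputs.I_plus_II / inputs.known_total


def estimate_total(inputs: CensusInputs) -> int:
    """Estimated total transcripts with coding potential (nearest integer)."""
    sn = sensitivity_known(inputs)
    if sn <= 0:
        raise ValueError("sensitivity must be positive to estimate a total")
    return round((inputs.I_plus_II + inputs.III + inputs.IV) / sn)


def precision_adjust(
    vmc_count: int,
    pcr_validated: int,
    pcr_assayed: int,
    use_rounded_percent: bool = True,
) -> int:
    """Expected true novel validated transcripts: VMC count x PCR precision.

    With ``use_rounded_percent`` the precision is first rounded to one
    decimal percentage point (the convention of the published worked
    example); otherwise the exact assay fraction is applied.
    """
    if pcr_assayed <= 0:
        raise ValueError("pcr_assayed must be positive")
    precision = pcr_validated / pcr_assayed
    if use_rounded_percent:
        precision = round(100.0 * precision, 1) / 100.0
    return round(vmc_count * precision)


def known_total_from_fraction(count: int, percent: float) -> int:
    """Recover a set size from a printed (subset count, percent) pair."""
    if not (0 < percent <= 100):
        raise ValueError("percent must be in (0, 100]")
    return round(count / (percent / 100.0))
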