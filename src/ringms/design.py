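"""Ring-trial sample design: the five-level algal/DOM mixing gradient plus
process blanks, and the mass-balance arithmetic behind the extract
preparation.

The mixing design spans pure algal extract (A), three algae-into-DOM
mixtures whose algal content follows a 45:15:5 gradient (A45M, A15M, A5M),
pure marine dissolved organic matter (M), and process blanks.  Internal
standards are spiked into the DOM pool and into the blanks, so the pure
algal sample A carries no standards.
"""

from __future__ import annotations

from dataclasses import dataclass

SAMPLE_TYPES = ("A", "A45M", "A15M", "A5M", "M", "blank")


@dataclass(frozen=True)
class SampleDesign:
    """One level of the mixing design.

    ``algal_fraction`` and ``dom_fraction`` are relative amounts of the two
    source extracts (1.0 = the full aliquot used for the endmember).
    """

    sample_type: str
    algal_fraction: float
    dom_fraction: float
    standards_spiked: bool
    replicates: int = 4

    def __post_init__(self) -> None:
        if self.sample_type not in SAMPLE_TYPES:
            raise ValueError(f"unknown sample type {self.sample_type!r}")
        if self.algal_fraction < 0 or self.dom_fraction < 0:
            raise ValueError("mixing fractions must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.sample_type == "A" and self.dom_fraction != 0:
            raise ValueError("sample A is algal extract only (dom_fraction = 0)")
        if self.sample_type == "M" and self.algal_fraction != 0:
            raise ValueError("sample M is DOM extract only (algal_fraction = 0)")
        if self.sample_type == "blank" and (self.algal_fraction or self.dom_fraction):
            raise ValueError("blanks carry neither algal nor DOM extract")


def default_design(replicates: int = 4) -> list[SampleDesign]:
    """The six-level design: A, A45M, A15M, A5M, M and process blanks.

    Algal content of the mixtures follows the 45:15:5 gradient
    (1 : 1/3 : 1/9 relative to the endmember aliquot).
    """
    return [
        SampleDesign("A", 1.0, 0.0, False, replicates),
        SampleDesign("A45M", 1.0, 1.0, True, replicates),
        SampleDesign("A15M", 1.0 / 3.0, 1.0, True, replicates),
        SampleDesign("A5M", 1.0 / 9.0, 1.0, True, replicates),
        SampleDesign("M", 0.0, 1.0, True, replicates),
        SampleDesign("blank", 0.0, 0.0, True, replicates),
    ]


def compute_design_concentrations(
    components,
    *,
    aliquot_volume: float | None = None,
    dilution_volume: float | None = None,
    molar_mass: float | None = None,
) -> float:
    """Mass-balance arithmetic for extract preparation (pure, no randomness).

    Parameters
    ----------
    components
        Iterable of ``(volume, concentration)`` pairs in mutually consistent
        units.  The total amount of analyte is ``sum(volume * concentration)``.
    aliquot_volume
        If given, the total amount is attributed back to the aliquot it was
        taken from and the *source* concentration is returned
        (``amount / aliquot_volume``).  Example: a 0.1 mL aliquot of an algal
        stock redissolved in 36.5 mL measuring 5.79 ug/mL carbon implies a
        stock concentration of 5.79 * 36.5 / 0.1 = 2113 ug/mL (2.1 mg/mL).
    dilution_volume
        If given (and no aliquot), returns the concentration after diluting
        the total amount into this volume.
    molar_mass
        If given, the summed amount is molar and is converted to mass by
        multiplying with ``molar_mass`` (g/mol); e.g. 30.0 umol/L of carbon
        in 2 L with 12.011 g/mol gives 720.7 ug (0.72 mg) per vial.

    Returns
    -------
    float
        A concentration (when an aliquot or dilution volume is supplied) or a
        total amount otherwise, consistent with the input units.
    """
    total = 0.0
    n = 0
    for volume, concentration in components:
        if volume <= 0:
            raise ValueError("volumes must be positive")
        if concentration < 0:
            raise ValueError("concentrations must be >= 0")
        total += float(volume) * float(concentration)
        n += 1
    if n == 0:
        raise ValueError("at least one (volume, concentration) component required")
    if molar_mass is not None:
        if molar_mass <= 0:
            raise ValueError("molar mass must be positive")
        total *= float(molar_mass)
    if aliquot_volume is not None:
        if aliquot_volume <= 0:
            raise ValueError("aliquot volume must be positive")
        return total / float(aliquot_volume)
    if dilution_volume is not None:
        if dilution_volume <= 0:
            raise ValueError("dilution volume must be positive")
        return total / float(dilution_volume)
    return total
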