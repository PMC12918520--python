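"""The eight spiked internal standards used for cross-laboratory QC.

Monoisotopic [M+H]+ masses computed from elemental formulas; reference
retention times are placed on the nominal 10-minute water/acetonitrile
gradient used throughout the simulator.  Fragment patterns are fixed,
synthetic surrogates (a handful of characteristic losses per compound) —
they stand in for real library spectra, which this package never ships.
"""

from __future__ import annotations

# name -> ([M+H]+ m/z in Da, reference RT in minutes on the 10-min gradient)
STANDARD_IONS = {
    "kainic_acid": (214.10739, 1.8),
    "domoic_acid": (312.14417, 2.4),
    "methamphetamine": (150.12773, 2.9),
    "imazapyr": (262.11862, 3.6),
    "cocaine": (304.15434, 4.3),
    "heroin": (370.16490, 5.1),
    "irgarol": (254.14339, 6.2),
    "isoxaben": (333.18088, 7.0),
}


def _fragments(mz: float) -> tuple[tuple[float, float], ...]:
    # Deterministic synthetic pattern: neutral losses of water, CO, and two
    # larger backbone losses, plus a low-mass reporter ion.
    return (
        (round(mz - 18.0106, 4), 1.0),
        (round(mz - 46.0055, 4), 0.6),
        (round(mz - 72.0211, 4), 0.35),
        (round(mz * 0.55, 4), 0.5),
        (round(mz * 0.31, 4), 0.25),
    )


def standard_library() -> list[dict]:
    """Reference list for QC matching: exactly 8 entries.

    Each entry carries ``name``, ``mz`` ([M+H]+), ``rt`` (minutes) and
    ``fragments`` (tuples of (m/z, relative intensity)).
    """
    return [
        {"name": name, "mz": mz, "rt": rt, "fragments": _fragments(mz)}
        for name, (mz, rt) in STANDARD_IONS.items()
    ]
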