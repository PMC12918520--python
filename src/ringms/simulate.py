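"""Synthetic multi-laboratory DDA ring-trial generator.

Emulates the statistical structure a cross-laboratory comparability analysis
has to cope with: a five-level algal/DOM mixing gradient plus process blanks,
eight spiked internal standards, laboratory-specific retention-time warps,
sensitivity, mass error and detection limits, intensity-biased top-k DDA
precursor selection with optional dynamic exclusion, chimeric MS/MS spectra
from co-elution inside the isolation window, and blank contaminants.

The model is deliberately minimal: chromatographic peaks are Gaussian in
time, abundance noise is multiplicative lognormal, and no isotope patterns,
adducts or profile-mode signal are produced.  See ``docs/methods.md``.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .design import SAMPLE_TYPES, SampleDesign
from .standards import standard_library
from .tables import FeatureTable

_SQRT_2PI = math.sqrt(2.0 * math.pi)

COMPOUND_CLASSES = ("algal", "dom", "contaminant", "standard")


@dataclass(frozen=True)
class GroundTruthCompound:
    """A true molecule in the simulated metabolome.

    ``fragments`` are (fragment m/z in Da, relative intensity in (0, 1]);
    ``base_abundance`` is the apex intensity in arbitrary units before lab
    effects; ``klass`` is one of algal / dom / contaminant / standard.
    """

    id: str
    ion_mz: float
    ref_rt: float
    peak_width: float
    fragments: tuple
    base_abundance: float
    klass: str
    annotation: str | None = None

    def __post_init__(self) -> None:
        if self.ion_mz <= 0:
            raise ValueError("ion_mz must be positive")
        if self.ref_rt <= 0:
            raise ValueError("ref_rt must be positive")
        if self.peak_width <= 0:
            raise ValueError("peak_width must be positive")
        if self.base_abundance <= 0:
            raise ValueError("base_abundance must be positive")
        if not self.fragments:
            raise ValueError("fragments must be non-empty")
        for _, rel in self.fragments:
            if not 0 < rel <= 1:
                raise ValueError("fragment relative intensities must be in (0, 1]")
        if self.klass not in COMPOUND_CLASSES:
            raise ValueError(f"unknown compound class {self.klass!r}")


@dataclass
class LabProfile:
    """One laboratory's instrument model.

    The retention-time warp is affine (``rt_slope * t + rt_offset``) plus an
    optional smooth cubic term ``rt_curve * (t / gradient_length)**3 *
    gradient_length`` whose deviation grows toward late retention times —
    outlier laboratories with 3-4 min late-gradient drift are modelled with
    ``rt_curve`` around 0.3 (deviation ``rt_curve * gradient_length`` at the
    end of the gradient).  ``cycle_time`` and ``exclusion_duration`` are in
    seconds; everything retention-related is in minutes.
    """

    lab_id: str
    rt_slope: float = 1.0
    rt_offset: float = 0.0
    rt_curve: float = 0.0
    rt_sigma: float = 0.05
    sensitivity: float = 1.0
    response_sigma: float = 0.6
    mass_error_ppm_bias: float = 0.0
    mass_error_ppm_sd: float = 2.0
    intensity_cv: float = 0.25
    cycle_time: float = 2.5
    top_k: int = 3
    dynamic_exclusion: bool = True
    exclusion_duration: float = 12.0
    detection_limit: float = 3000.0
    isolation_width: float = 1.0
    gradient_length: float = 10.0
    background_level: float = 0.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.cycle_time <= 0:
            raise ValueError("cycle_time must be positive")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.exclusion_duration < 0:
            raise ValueError("exclusion_duration must be >= 0")
        if self.isolation_width <= 0:
            raise ValueError("isolation_width must be positive")
        if self.rt_sigma < 0 or self.intensity_cv < 0 or self.response_sigma < 0:
            raise ValueError("noise scales must be >= 0")
        if self.sensitivity <= 0:
            raise ValueError("sensitivity must be positive")
        if self.detection_limit < 0:
            raise ValueError("detection_limit must be >= 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        grid = np.linspace(0.0, self.gradient_length + 2.0, 257)
        warped = self.rt_warp(grid)
        if not np.all(np.diff(warped) > 0):
            raise ValueError("rt_warp must be strictly increasing")

    def rt_warp(self, rt):
        rt = np.asarray(rt, dtype=float)
        g = self.gradient_length
        return self.rt_slope * rt + self.rt_offset + self.rt_curve * (rt / g) ** 3 * g

    def background(self, mz: float, rt: float) -> float:
        """Unresolved refractory-DOM background intensity co-isolated in one
        isolation window, strongest in the m/z 400-600 hump mid-gradient.
        Dilutes precursor purity but is never itself selected for MS/MS."""
        if self.background_level == 0.0:
            return 0.0
        g = self.gradient_length
        mz_hump = math.exp(-0.5 * ((mz - 500.0) / 150.0) ** 2)
        rt_env = math.exp(-0.5 * ((rt - 0.55 * g) / (0.35 * g)) ** 2)
        return self.background_level * (0.2 + 0.8 * mz_hump) * rt_env


@dataclass
class MsmsEvent:
    """One DDA MS/MS acquisition event."""

    precursor_mz: float
    trigger_rt: float
    precursor_intensity: float
    purity: float
    source_compound: str | None
    fragments: tuple
    lab_id: str | None = None
    sample_id: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.purity <= 1.0:
            raise ValueError("purity must be in [0, 1]")
        if self.precursor_intensity < 0:
            raise ValueError("precursor_intensity must be >= 0")


# ---------------------------------------------------------------------------
# Ground truth
# ---------------------------------------------------------------------------

def make_ground_truth(
    n_algal: int,
    n_dom: int,
    n_contaminant: int,
    seed: int,
    annotation_fraction: float = 0.10,
    gradient_length: float = 10.0,
) -> list[GroundTruthCompound]:
    """Draw a synthetic metabolome; the 8 internal standards are always appended.

    Base abundances are lognormal (a small high-intensity head over a long
    low-intensity tail).  DOM compounds are enriched at m/z 400-600, the
    characteristic ion range of marine DOM; algal and contaminant ions are
    spread over m/z 100-800.  Library annotations are assigned with
    probability increasing in abundance (averaging ``annotation_fraction``):
    in real non-targeted data it is the intense peaks that match spectral
    libraries, because weak ions are rarely fragmented and match poorly.
    Deterministic given ``seed``.
    """
    for name, n in (("n_algal", n_algal), ("n_dom", n_dom), ("n_contaminant", n_contaminant)):
        if n < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    compounds: list[GroundTruthCompound] = []

    def _draw(prefix: str, klass: str, n: int, mz_draw, log_mean: float, log_sigma: float):
        for i in range(n):
            mz = float(mz_draw())
            rt = float(rng.uniform(0.8, gradient_length - 0.3))
            width = float(rng.uniform(0.03, 0.08))
            base = float(rng.lognormal(log_mean, log_sigma))
            n_frag = int(rng.integers(4, 9))
            frag_mz = np.sort(rng.uniform(50.0, max(60.0, mz - 20.0), n_frag))
            frag_int = rng.uniform(0.05, 1.0, n_frag)
            frag_int = frag_int / frag_int.max()
            # intense compounds are the ones that match spectral libraries
            percentile = sps.norm.cdf((math.log(base) - log_mean) / log_sigma)
            annotated = rng.random() < min(2.0 * annotation_fraction * percentile, 1.0)
            cid = f"{prefix}{i:04d}"
            compounds.append(
                GroundTruthCompound(
                    id=cid,
                    ion_mz=mz,
                    ref_rt=rt,
                    peak_width=width,
                    fragments=tuple(zip(frag_mz.round(4).tolist(), frag_int.round(4).tolist())),
                    base_abundance=base,
                    klass=klass,
                    annotation=f"lib_{cid}" if annotated else None,
                )
            )

    _draw("alg", "algal", n_algal, lambda: rng.uniform(100.0, 800.0), math.log(1.2e4), 1.5)
    _draw(
        "dom",
        "dom",
        n_dom,
        lambda: float(np.clip(rng.normal(500.0, 60.0), 100.0, 800.0)),
        math.log(8.0e3),
        1.5,
    )
    _draw("con", "contaminant", n_contaminant, lambda: rng.uniform(100.0, 800.0), math.log(4.0e4), 1.0)

    for entry in standard_library():
        compounds.append(
            GroundTruthCompound(
                id=entry["name"],
                ion_mz=entry["mz"],
                ref_rt=entry["rt"],
                peak_width=0.05,
                fragments=entry["fragments"],
                base_abundance=4.0e5,
                klass="standard",
                annotation=entry["name"],
            )
        )
    return compounds


def default_lab_panel(
    n_labs: int = 15,
    seed: int = 0,
    response_sigma: float = 0.6,
    n_rt_outliers: int = 3,
) -> list[LabProfile]:
    """A panel of laboratory profiles mirroring a real ring trial.

    Most laboratories deviate by well under a minute in retention time; the
    last ``n_rt_outliers`` labs carry a cubic drift reaching 3-4 minutes at
    the end of the gradient.  Sensitivity, mass accuracy, duty cycle and
    detection limit all vary lab to lab.
    """
    if n_labs < 1:
        raise ValueError("n_labs must be >= 1")
    rng = np.random.default_rng(seed)
    letters = string.ascii_lowercase
    profiles = []
    for i in range(n_labs):
        lab_id = f"lab_{letters[i % 26]}{'' if i < 26 else i // 26}"
        outlier = i >= n_labs - n_rt_outliers
        profiles.append(
            LabProfile(
                lab_id=lab_id,
                rt_slope=float(rng.uniform(0.96, 1.04)),
                rt_offset=float(np.clip(rng.normal(0.0, 0.25), -0.6, 0.6)),
                rt_curve=float(rng.uniform(0.25, 0.40)) if outlier else 0.0,
                rt_sigma=float(rng.uniform(0.02, 0.08)),
                sensitivity=float(rng.lognormal(0.0, 0.4)),
                response_sigma=response_sigma,
                mass_error_ppm_bias=float(rng.normal(0.0, 1.5)),
                mass_error_ppm_sd=float(rng.uniform(0.5, 2.0)),
                intensity_cv=float(rng.uniform(0.15, 0.35)),
                cycle_time=float(rng.uniform(2.0, 3.5)),
                top_k=int(rng.integers(3, 6)),
                dynamic_exclusion=True,
                exclusion_duration=float(rng.uniform(8.0, 20.0)),
                detection_limit=float(rng.lognormal(math.log(1.5e4), 0.5)),
                isolation_width=1.0,
                background_level=float(rng.lognormal(math.log(6.0e3), 0.6)),
            )
        )
    return profiles


# ---------------------------------------------------------------------------
# DDA engine
# ---------------------------------------------------------------------------

def _normalize_trace(ms1_trace):
    """Coerce a trace into per-cycle (rt, mz, intensity, compound) arrays."""
    cycles = []
    for cycle in ms1_trace:
        rt, payload = cycle[0], cycle[1:]
        if len(payload) == 3:
            mz, inten, comp = payload
            mz = np.asarray(mz, dtype=float)
            inten = np.asarray(inten, dtype=float)
            comp = np.asarray(comp, dtype=object)
        else:
            peaks = list(payload[0])
            mz = np.array([p[0] for p in peaks], dtype=float)
            inten = np.array([p[1] for p in peaks], dtype=float)
            comp = np.array(
                [p[2] if len(p) > 2 else None for p in peaks], dtype=object
            )
        cycles.append((float(rt), mz, inten, comp))
    return cycles


def _chimeric_fragments(mz, inten, comp, window_mask, fragment_map):
    """Intensity-weighted union of fragments of all compounds in the window."""
    frag_mz: list[np.ndarray] = []
    frag_int: list[np.ndarray] = []
    for j in np.flatnonzero(window_mask):
        cid = comp[j]
        if cid is None or cid not in fragment_map:
            continue
        fmz, fint = fragment_map[cid]
        frag_mz.append(fmz)
        frag_int.append(fint * inten[j])
    if not frag_mz:
        return ()
    all_mz = np.concatenate(frag_mz)
    all_int = np.concatenate(frag_int)
    order = np.argsort(all_mz)
    all_mz, all_int = all_mz[order], all_int[order]
    all_int = all_int / all_int.max()
    return tuple(zip(all_mz.round(4).tolist(), all_int.round(6).tolist()))


def simulate_dda(ms1_trace, profile: LabProfile, fragment_map: dict | None = None) -> list[MsmsEvent]:
    """Replay top-k DDA precursor selection over an MS1 trace.

    ``ms1_trace`` is a time-ordered sequence of cycles, each either
    ``(rt_minutes, peaks)`` with peaks iterable of ``(mz, intensity[,
    compound_id])`` or ``(rt, mz_array, intensity_array, compound_array)``.
    Per cycle the ``top_k`` most intense precursors above the detection limit
    and not currently excluded are fragmented; with dynamic exclusion each
    selected precursor m/z (+- isolation_width/2) is barred for
    ``exclusion_duration`` seconds.  Event purity is the precursor's share of
    summed MS1 intensity within the isolation window (closed lower, open
    upper edge), and fragments are the intensity-weighted union over all
    co-isolated compounds (chimerism).
    """
    profile.validate()
    cycles = _normalize_trace(ms1_trace)
    if any(cycles[i][0] > cycles[i + 1][0] for i in range(len(cycles) - 1)):
        raise ValueError("MS1 cycles must be ordered in time")
    fragment_map = fragment_map or {}
    half = profile.isolation_width / 2.0
    excl_mz: list[float] = []
    excl_until: list[float] = []
    events: list[MsmsEvent] = []
    for rt, mz, inten, comp in cycles:
        if mz.size == 0:
            continue
        # prune expired exclusions
        if excl_mz:
            keep = [u > rt for u in excl_until]
            excl_mz = [m for m, k in zip(excl_mz, keep) if k]
            excl_until = [u for u, k in zip(excl_until, keep) if k]
        eligible = inten > profile.detection_limit
        if excl_mz and eligible.any():
            centers = np.asarray(excl_mz)
            blocked = (np.abs(mz[:, None] - centers[None, :]) < half).any(axis=1)
            eligible &= ~blocked
        idx = np.flatnonzero(eligible)
        if idx.size == 0:
            continue
        order = np.lexsort((mz[idx], -inten[idx]))
        chosen = idx[order[: profile.top_k]]
        for j in chosen:
            window = (mz >= mz[j] - half) & (mz < mz[j] + half)
            total = float(inten[window].sum()) + profile.background(float(mz[j]), rt)
            purity = float(inten[j]) / total if total > 0 else 0.0
            events.append(
                MsmsEvent(
                    precursor_mz=float(mz[j]),
                    trigger_rt=rt,
                    precursor_intensity=float(inten[j]),
                    purity=min(purity, 1.0),
                    source_compound=comp[j],
                    fragments=_chimeric_fragments(mz, inten, comp, window, fragment_map),
                    lab_id=profile.lab_id,
                )
            )
            if profile.dynamic_exclusion:
                excl_mz.append(float(mz[j]))
                excl_until.append(rt + profile.exclusion_duration / 60.0)
    return events


# ---------------------------------------------------------------------------
# Laboratory simulation
# ---------------------------------------------------------------------------

def _class_fraction(compound: GroundTruthCompound, d: SampleDesign, contaminant_sample_scale: float) -> float:
    if compound.klass == "algal":
        return d.algal_fraction
    if compound.klass == "dom":
        return d.dom_fraction
    if compound.klass == "contaminant":
        # contaminants ride along in every injection, blanks included
        return 1.0 if d.sample_type == "blank" else contaminant_sample_scale
    return 1.0 if d.standards_spiked else 0.0  # standard


def simulate_lab(
    truth: list[GroundTruthCompound],
    design: list[SampleDesign],
    profile: LabProfile,
    seed: int,
    run_length: float = 11.0,
    contaminant_sample_scale: float = 1.0,
    with_dda: bool = True,
    with_spectra: bool = True,
):
    """Simulate one laboratory's ring-trial acquisition.

    Returns ``(FeatureTable, events, spectra)``.  Feature intensities are
    FBMN-style chromatographic peak areas (apex x width x sqrt(2 pi)) for
    compounds whose apex clears the detection limit; ``events`` is the DDA
    MS/MS log across all injections and ``spectra`` the MGF-ready spectrum
    dicts.  Bit-identical for identical arguments.
    """
    profile.validate()
    types_present = {d.sample_type for d in design}
    missing = set(SAMPLE_TYPES) - types_present
    if missing:
        raise ValueError(f"design must cover all six sample types; missing {sorted(missing)}")
    if len(types_present) != len(design):
        raise ValueError("duplicate sample types in design")

    rng = np.random.default_rng(seed)
    n = len(truth)
    base = np.array([c.base_abundance for c in truth])
    widths = np.array([c.peak_width for c in truth])
    ref_rt = np.array([c.ref_rt for c in truth])
    ion_mz = np.array([c.ion_mz for c in truth])

    # lab-level per-compound effects (one feature per compound per lab)
    response = rng.lognormal(0.0, profile.response_sigma, n) if profile.response_sigma else np.ones(n)
    ppm = profile.mass_error_ppm_bias + rng.normal(0.0, profile.mass_error_ppm_sd, n)
    obs_mz = ion_mz * (1.0 + ppm * 1e-6)
    obs_rt = np.maximum(
        np.asarray(profile.rt_warp(ref_rt)) + rng.normal(0.0, profile.rt_sigma, n), 0.05
    )

    samples: list[str] = []
    sample_type: list[str] = []
    is_blank: list[bool] = []
    frac_cols: list[np.ndarray] = []
    for d in design:
        frac = np.array([_class_fraction(c, d, contaminant_sample_scale) for c in truth])
        for r in range(1, d.replicates + 1):
            samples.append(f"{d.sample_type}_{r}")
            sample_type.append(d.sample_type)
            is_blank.append(d.sample_type == "blank")
            frac_cols.append(frac)
    frac_matrix = np.column_stack(frac_cols)
    noise = rng.lognormal(0.0, profile.intensity_cv, size=(n, len(samples)))
    apex = base[:, None] * frac_matrix * profile.sensitivity * response[:, None] * noise
    apex[frac_matrix == 0] = 0.0

    detected = apex > profile.detection_limit
    areas = np.where(detected, apex * widths[:, None] * _SQRT_2PI, 0.0)

    keep = detected.any(axis=1)
    feature_ids = [f"F{i:05d}" for i in range(int(keep.sum()))]
    kept_idx = np.flatnonzero(keep)
    intensities = pd.DataFrame(areas[kept_idx], index=feature_ids, columns=samples)
    features = pd.DataFrame(
        {
            "mz": obs_mz[kept_idx],
            "rt": obs_rt[kept_idx],
            "annotation": [truth[i].annotation for i in kept_idx],
            "compound": [truth[i].id for i in kept_idx],
            "klass": [truth[i].klass for i in kept_idx],
        },
        index=feature_ids,
    )
    sample_meta = pd.DataFrame(
        {"sample_type": sample_type, "is_blank": is_blank}, index=pd.Index(samples, name="sample")
    )
    table = FeatureTable(intensities, features, sample_meta, lab_id=profile.lab_id)

    events: list[MsmsEvent] = []
    if with_dda:
        fragment_map = {
            c.id: (
                np.array([f[0] for f in c.fragments]),
                np.array([f[1] for f in c.fragments]),
            )
            for c in truth
        }
        comp_ids = np.array([c.id for c in truth], dtype=object)
        cycle_rt = np.arange(0.0, run_length * 60.0, profile.cycle_time) / 60.0
        floor = max(1.0, profile.detection_limit * 0.01)
        for s_idx, sample_id in enumerate(samples):
            amp = apex[:, s_idx]
            active = amp > floor
            if not active.any():
                continue
            a_amp = amp[active]
            a_rt = obs_rt[active]
            a_w = widths[active]
            a_mz = obs_mz[active]
            a_comp = comp_ids[active]
            profile_matrix = a_amp[:, None] * np.exp(
                -0.5 * ((cycle_rt[None, :] - a_rt[:, None]) / a_w[:, None]) ** 2
            )
            trace = []
            for t_idx, rt in enumerate(cycle_rt):
                col = profile_matrix[:, t_idx]
                mask = col > floor
                if not mask.any():
                    continue
                trace.append((float(rt), a_mz[mask], col[mask], a_comp[mask]))
            sample_events = simulate_dda(trace, profile, fragment_map)
            for ev in sample_events:
                ev.sample_id = sample_id
            events.extend(sample_events)

    spectra = events_to_spectra(events) if with_spectra else []
    return table, events, spectra


def events_to_spectra(events: list[MsmsEvent]) -> list[dict]:
    """Convert MS/MS events to pyteomics-style MGF spectrum dicts."""
    spectra = []
    for i, ev in enumerate(events):
        fmz = np.array([f[0] for f in ev.fragments], dtype=float)
        fint = np.array([f[1] for f in ev.fragments], dtype=float)
        spectra.append(
            {
                "m/z array": fmz,
                "intensity array": fint,
                "params": {
                    "title": f"{ev.lab_id or 'lab'}.{ev.sample_id or 'sample'}.scan={i}"
                    + (f".compound={ev.source_compound}" if ev.source_compound else ""),
                    "pepmass": (round(ev.precursor_mz, 6), round(ev.precursor_intensity, 4)),
                    "rtinseconds": round(ev.trigger_rt * 60.0, 3),
                    "charge": "1+",
                },
            }
        )
    return spectra


def simulate_ring_trial(
    truth: list[GroundTruthCompound],
    design: list[SampleDesign],
    panel: list[LabProfile],
    seed: int,
    **kwargs,
) -> dict:
    """Simulate every laboratory in a panel; returns lab_id -> (table, events, spectra).

    Per-lab seeds are spawned deterministically from ``seed``.
    """
    if len({p.lab_id for p in panel}) != len(panel):
        raise ValueError("duplicate lab ids in panel")
    child_seeds = np.random.SeedSequence(seed).generate_state(len(panel)) % (2**31)
    return {
        p.lab_id: simulate_lab(truth, design, p, int(child_seeds[i]), **kwargs)
        for i, p in enumerate(panel)
    }
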