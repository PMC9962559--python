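"""Synthetic LF-NMR data generator for the oil-oxidation classifier.

No public database of labeled CPMG relaxation curves for oxidized oils
exists, so this module fabricates the study conditions: multi-exponential
CPMG echo trains whose T2 components shorten with oxidation (and gain a
short-T2 oxidation-product component in heavily oxidized oil), PFGSE
attenuation series governed by the self-diffusion coefficient D, and a
chemistry panel (PV, p-AV) drawn inside the class bins so that every
sample's ground-truth label re-derives from its own chemistry.

The decay model is the standard time-domain NMR picture: a small number
of proton populations (rigidity/mobility segments of the triacylglycerol
matrix), each relaxing monoexponentially, summed with additive Gaussian
noise that shrinks as 1/sqrt(n_scans) under scan averaging:

    S(t_k) = sum_i a_i * exp(-t_k / T2_i) + eps_k,   t_k = 2*tau*k.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .curves import RelaxationCurve, write_curve
from .errors import ConfigurationError, InvalidInputError
from .labels import TABLE_BINS, ChemAssay, OxidationClass, classify_oxidation

#: 1H gyromagnetic ratio, rad s^-1 T^-1.
GAMMA_H = 2.675e8


@dataclass(frozen=True)
class AcquisitionConfig:
    """CPMG acquisition settings.

    ``tau`` is the echo half-spacing in seconds (instrument practice:
    200-550 us); the k-th echo is sampled at t_k = 2*tau*k.  Full
    instrument echo trains run to 16,384 echoes; the default 2,048 keeps
    desk-scale simulation and training fast and is pooled downstream
    anyway.  ``noise_sigma`` is the additive Gaussian noise sd relative
    to unit initial amplitude, reduced by averaging over ``n_scans``.
    """

    tau: float = 4.0e-4
    n_echoes: int = 2048
    noise_sigma: float = 0.01
    n_scans: int = 1

    def __post_init__(self):
        if self.tau <= 0:
            raise InvalidInputError("tau must be positive")
        if self.n_echoes < 1:
            raise InvalidInputError("n_echoes must be >= 1")
        if self.noise_sigma < 0:
            raise InvalidInputError("noise_sigma must be >= 0")
        if self.n_scans < 1:
            raise InvalidInputError("n_scans must be >= 1")

    @property
    def times(self) -> np.ndarray:
        return 2.0 * self.tau * np.arange(1, self.n_echoes + 1)


@dataclass(frozen=True)
class ComponentSpec:
    """One relaxing proton population: signal fraction and T2 in seconds."""

    amplitude: float
    t2: float

    def __post_init__(self):
        if self.amplitude < 0:
            raise InvalidInputError("amplitude must be >= 0")
        if self.t2 <= 0:
            raise InvalidInputError("t2 must be positive")


@dataclass(frozen=True)
class PfgseConfig:
    """Pulsed-field-gradient spin-echo settings (Stejskal-Tanner b-factor).

    b = gamma^2 G^2 delta^2 (Delta - delta/3) for gradient strength G,
    duration delta and separation Delta.  Defaults mirror benchtop
    practice: Delta = 7.5 ms, delta = 0.5 ms, G stepped up to 1.6 T/m.
    """

    big_delta: float = 7.5e-3
    small_delta: float = 5.0e-4
    gradient_steps: tuple = tuple(np.linspace(0.0, 1.6, 9))
    gamma: float = GAMMA_H

    def __post_init__(self):
        if not (self.big_delta > self.small_delta / 3.0 > 0):
            raise InvalidInputError("require big_delta > small_delta/3 > 0")
        if any(g < 0 for g in self.gradient_steps):
            raise InvalidInputError("gradient strengths must be >= 0")
        object.__setattr__(self, "gradient_steps", tuple(float(g) for g in self.gradient_steps))

    def b_values(self) -> np.ndarray:
        g = np.asarray(self.gradient_steps)
        return (self.gamma ** 2) * (g ** 2) * (self.small_delta ** 2) * (
            self.big_delta - self.small_delta / 3.0
        )


@dataclass(frozen=True)
class OxidationStateParams:
    """Class-conditional generator parameters.

    ``component_means`` are the mean proton populations for the class;
    each sample multiplies amplitudes and T2 values by lognormal-like
    jitter of relative sd ``component_jitter``.  Chemistry (``d_range``,
    ``pv_range``, ``pav_range``) is drawn uniformly inside intervals that
    sit strictly inside the class's decision bins, so ground-truth labels
    are consistent by construction.
    """

    class_label: OxidationClass
    component_means: tuple
    component_jitter: float = 0.05
    d_range: tuple = (0.0, 0.0)      # m^2/s
    pv_range: tuple = (0.0, 0.0)     # mmol/kg
    pav_range: tuple = (0.0, 0.0)    # dimensionless
    boundary_blur: float = 0.0       # 0 = uniform draws; >0 concentrates
                                     # chemistry in that outer fraction of
                                     # each range, near the bin edges

    def __post_init__(self):
        for name in ("d_range", "pv_range", "pav_range"):
            lo, hi = getattr(self, name)
            if not (lo <= hi):
                raise InvalidInputError(f"{name} must be a non-empty interval")
        if self.component_jitter < 0:
            raise InvalidInputError("component_jitter must be >= 0")
        if not 0 <= self.boundary_blur <= 0.5:
            raise InvalidInputError("boundary_blur must be in [0, 0.5]")
        if len(self.component_means) == 0:
            raise InvalidInputError("component_means must be non-empty")
        # both interval endpoints must classify to this class on each single
        # criterion, so sampled chemistry can never cross a bin boundary
        for d in self.d_range:
            if TABLE_BINS.classify_d(d) != self.class_label:
                raise ConfigurationError("d_range leaves the class's diffusion bin")
        for pv in self.pv_range:
            if TABLE_BINS.classify_pv(pv) != self.class_label:
                raise ConfigurationError("pv_range leaves the class's peroxide bin")


def _components(spec_pairs) -> tuple:
    return tuple(ComponentSpec(a, t2) for a, t2 in spec_pairs)


# Default class-conditional parameter sets.  Four segmental proton
# populations for fresh oil; partially oxidized oil shortens every T2 by
# ~20%, heavily oxidized oil by ~40% and adds a short-T2 (~20 ms)
# oxidation-product population.  These are generator choices consistent
# with the qualitative T2 shortening seen in thermally oxidized linseed
# oil, not measured values.
_GOOD_T2 = (0.08, 0.13, 0.19, 0.26)
_AMPS = (0.15, 0.30, 0.35, 0.20)

DEFAULT_STATE_PARAMS: dict[OxidationClass, OxidationStateParams] = {
    OxidationClass.GOOD: OxidationStateParams(
        class_label=OxidationClass.GOOD,
        component_means=_components(zip(_AMPS, _GOOD_T2)),
        d_range=(0.031e-9, 0.040e-9),
        pv_range=(4.0, 19.0),
        pav_range=(2.0, 10.0),
    ),
    OxidationClass.FAIR: OxidationStateParams(
        class_label=OxidationClass.FAIR,
        component_means=_components(zip(_AMPS, (0.8 * t for t in _GOOD_T2))),
        d_range=(0.0205e-9, 0.030e-9),
        pv_range=(20.0, 49.0),
        pav_range=(10.0, 25.0),
    ),
    OxidationClass.BAD: OxidationStateParams(
        class_label=OxidationClass.BAD,
        component_means=_components(
            [(0.15, 0.02)] + [(0.85 * a, 0.6 * t) for a, t in zip(_AMPS, _GOOD_T2)]
        ),
        d_range=(0.008e-9, 0.020e-9),
        pv_range=(50.0, 150.0),
        pav_range=(25.0, 60.0),
    ),
}


def simulate_cpmg_curve(
    components, acq: AcquisitionConfig, seed: int | None = 0
) -> RelaxationCurve:
    """Simulate one CPMG echo train from a list of :class:`ComponentSpec`.

    Noise is Gaussian with sd ``noise_sigma / sqrt(n_scans)``, the
    residual noise after coherent scan averaging.  Deterministic given
    ``seed``.
    """
    components = list(components)
    if not components:
        raise InvalidInputError("component list must be non-empty")
    t = acq.times
    amps = np.array([c.amplitude for c in components])
    t2s = np.array([c.t2 for c in components])
    signal = np.sum(amps[None, :] * np.exp(-t[:, None] / t2s[None, :]), axis=1)
    if acq.noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, acq.noise_sigma / np.sqrt(acq.n_scans), size=t.size)
    meta = {"tau_s": acq.tau, "n_echoes": acq.n_echoes, "n_scans": acq.n_scans}
    return RelaxationCurve(t, signal, meta=meta)


def simulate_pfgse(
    d: float, cfg: PfgseConfig, noise_sigma: float = 0.0, seed: int | None = 0
) -> np.ndarray:
    """Simulate a PFGSE attenuation series for diffusion coefficient ``d``.

    Returns an (n, 2) array of ``(b, relative signal)`` pairs following
    the Stejskal-Tanner attenuation exp(-b*d); a b = 0 reference point is
    included (value exactly 1 before noise).
    """
    if d <= 0:
        raise InvalidInputError("d must be positive")
    b = cfg.b_values()
    if 0.0 not in cfg.gradient_steps:
        b = np.concatenate([[0.0], b])
    signal = np.exp(-b * d)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sigma, size=b.size)
    return np.column_stack([b, signal])


def sample_oxidation_state(
    class_label: OxidationClass, params: OxidationStateParams, seed: int | None = 0
):
    """Draw one sample's proton populations and chemistry for a class.

    Component amplitudes and T2 values get multiplicative jitter of
    relative sd ``component_jitter`` (clipped to stay positive);
    chemistry is uniform within the class ranges.  Returns
    ``(components, ChemAssay)``.
    """
    if params.class_label != class_label:
        raise InvalidInputError(
            f"params are for class {params.class_label.label}, not {class_label.label}"
        )
    rng = np.random.default_rng(seed)
    comps = []
    for c in params.component_means:
        if params.component_jitter > 0:
            fa = max(1.0 + params.component_jitter * rng.standard_normal(), 0.05)
            ft = max(1.0 + params.component_jitter * rng.standard_normal(), 0.05)
        else:
            fa = ft = 1.0
        comps.append(ComponentSpec(c.amplitude * fa, c.t2 * ft))
    def draw(lo, hi):
        if params.boundary_blur <= 0 or lo == hi:
            return rng.uniform(lo, hi)
        # pick one edge of the class range and draw uniformly inside the
        # blur fraction next to it; ranges stay inside the class bin, so
        # labels remain unambiguous while chemistry crowds the thresholds
        width = (hi - lo) * params.boundary_blur
        return (rng.uniform(lo, lo + width) if rng.random() < 0.5
                else rng.uniform(hi - width, hi))

    d = draw(*params.d_range)
    pv = draw(*params.pv_range)
    pav = draw(*params.pav_range)
    return tuple(comps), ChemAssay(pv=pv, pav=pav, d=d)


@dataclass(frozen=True)
class SampleRecord:
    """One labeled synthetic sample: curve, PFGSE series, chemistry, class."""

    sample_id: str
    curve: RelaxationCurve
    pfgse: np.ndarray
    chem: ChemAssay
    true_class: OxidationClass
    seed: int

    def manifest_entry(self, curve_path: str | None = None) -> dict:
        entry = {"sample_id": self.sample_id, "class": self.true_class.label,
                 "seed": int(self.seed)}
        entry.update(self.chem.to_dict())
        entry.update({k: self.curve.meta.get(k) for k in ("tau_s", "n_echoes", "n_scans")})
        if curve_path is not None:
            entry["curve_path"] = curve_path
        return entry


def _class_counts(n: int, class_mix) -> dict[OxidationClass, int]:
    mix = np.asarray(class_mix, dtype=float)
    if mix.size != 3 or np.any(mix < 0):
        raise InvalidInputError("class_mix must be three non-negative proportions")
    total = mix.sum()
    if not np.isclose(total, 1.0, atol=1e-6):
        mix = mix / total  # accept raw proportions such as Table-style supports
    n_nonzero = int(np.sum(mix > 0))
    if n < n_nonzero:
        raise InvalidInputError("n is smaller than the number of classes with nonzero proportion")
    # largest-remainder rounding keeps the total exactly n
    raw = n * mix
    counts = np.floor(raw).astype(int)
    remainder = raw - counts
    for idx in np.argsort(-remainder)[: n - counts.sum()]:
        counts[idx] += 1
    return {OxidationClass(i): int(counts[i]) for i in range(3)}


def generate_dataset(
    n: int,
    class_mix=(126 / 390, 77 / 390, 187 / 390),
    acq: AcquisitionConfig | None = None,
    pfgse_cfg: PfgseConfig | None = None,
    seed: int = 0,
    state_params: dict[OxidationClass, OxidationStateParams] | None = None,
    pfgse_noise_sigma: float = 1e-4,
) -> list[SampleRecord]:
    """Generate ``n`` labeled samples with per-class counts from ``class_mix``.

    ``class_mix`` is ordered (Good, Fair, Bad) and may be given as raw
    supports; counts use largest-remainder rounding.  Fully reproducible
    from ``seed``: per-sample seeds are drawn once from the master RNG.
    """
    if n < 3:
        raise InvalidInputError("n must be >= 3")
    acq = acq or AcquisitionConfig()
    pfgse_cfg = pfgse_cfg or PfgseConfig()
    state_params = state_params or DEFAULT_STATE_PARAMS
    counts = _class_counts(n, class_mix)
    rng = np.random.default_rng(seed)
    records: list[SampleRecord] = []
    idx = 0
    for cls in OxidationClass:
        params = state_params[cls]
        for _ in range(counts[cls]):
            s = int(rng.integers(0, 2**31 - 1))
            comps, chem = sample_oxidation_state(cls, params, seed=s)
            curve = simulate_cpmg_curve(comps, acq, seed=s + 1)
            pfgse = simulate_pfgse(chem.d, pfgse_cfg, noise_sigma=pfgse_noise_sigma, seed=s + 2)
            derived = classify_oxidation(chem.d, chem.pv)
            assert derived == cls, "generator invariant: chemistry must re-derive the label"
            records.append(SampleRecord(
                sample_id=f"S{idx:04d}", curve=curve, pfgse=pfgse,
                chem=chem, true_class=cls, seed=s,
            ))
            idx += 1
    return records


def write_dataset(records: list[SampleRecord], out_dir: str | Path) -> Path:
    """Write curve files and a JSON manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    curve_dir = out_dir / "curves"
    curve_dir.mkdir(parents=True, exist_ok=True)
    manifest = []
    for rec in records:
        rel = f"curves/{rec.sample_id}.csv"
        write_curve(rec.curve, out_dir / rel)
        manifest.append(rec.manifest_entry(curve_path=rel))
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return path
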