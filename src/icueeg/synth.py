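"""Synthetic ICU-EEG cohort generation.

Real early-EEG monitoring data from intensive-care patients cannot be shared,
so every downstream stage of this package is exercised on synthetic
recordings whose *statistical structure* is controllable: band powers, the
1/f^alpha aperiodic background, interhemispheric asymmetry, slow
amplitude-envelope dynamics with a prescribed Hurst exponent, band-power
variability over time, and outcome-coupled effect sizes at the cohort level.

Construction
------------
Each channel is the sum of

* an aperiodic background: Gaussian noise spectrally shaped to a one-sided
  PSD ``10**offset * f**(-alpha)`` (flat below 0.5 Hz), synthesized with
  random Fourier phases;
* one narrowband oscillation per frequency band: white noise band-passed by
  a 4th-order zero-phase Butterworth (independent per channel), amplitude-
  modulated by a *shared-across-channels* positive envelope ``1 + m*z`` where
  ``z`` is fractional Gaussian noise with the requested Hurst exponent and
  ``m`` is the variability knob.  Sharing the envelope across channels mimics
  global arousal-level modulation and makes the channel-summed envelope carry
  the prescribed long-range temporal correlations.

Interhemispheric asymmetry multiplies right-hemisphere channels by the gain
``(1 + a) / (1 - a)``, which maps ``a`` in [0, 1) monotonically onto the
[0, 1) range of the brain symmetry index.

Fractional Gaussian noise is synthesized by circulant embedding of the exact
fGn autocovariance, so the generator doubles as the independent oracle for
the detrended-fluctuation-analysis estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import fft as sfft

from .bands import BANDS
from .io import Recording
from .montage import STANDARD_1020, homologous_indices, right_indices

__all__ = [
    "EEGProfile",
    "CohortSpec",
    "Cohort",
    "CovariateSpec",
    "DEFAULT_COVARIATE_MODEL",
    "DEFAULT_EFFECT_SIZES",
    "generate_fgn",
    "fgn_autocovariance",
    "generate_recording",
    "inject_artifacts",
    "generate_cohort",
    "export_cohort",
]


# ---------------------------------------------------------------------------
# fractional Gaussian noise
# ---------------------------------------------------------------------------

def fgn_autocovariance(h: float, n: int) -> np.ndarray:
    """Exact autocovariance gamma(k), k = 0..n-1, of unit-variance fGn."""
    k = np.arange(n, dtype=float)
    return 0.5 * (
        np.abs(k + 1) ** (2 * h) - 2 * np.abs(k) ** (2 * h) + np.abs(k - 1) ** (2 * h)
    )


def generate_fgn(h: float, n: int, seed: "int | np.random.Generator | None" = None
                 ) -> np.ndarray:
    """Sample ``n`` points of unit-variance fractional Gaussian noise.

    Uses circulant embedding (Davies-Harte), which reproduces the fGn
    autocovariance exactly; ``h = 0.5`` reduces to white noise, ``h > 0.5``
    gives persistent (long-range correlated) increments.

    Raises
    ------
    ValueError
        If ``h`` is outside the open interval (0, 1).
    """
    if not 0.0 < h < 1.0:
        raise ValueError(f"Hurst exponent must be in (0, 1), got {h}")
    if n < 1:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if h == 0.5:
        return rng.standard_normal(n)
    # pad the embedding length to an FFT-friendly size, then truncate
    n_gen = sfft.next_fast_len(n)
    gamma = fgn_autocovariance(h, n_gen + 1)
    # first row of the 2n-circulant embedding
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = sfft.fft(row).real
    lam = np.clip(lam, 0.0, None)  # tiny negatives from roundoff
    m = row.size
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    x = sfft.fft(np.sqrt(lam / m) * z)
    return x.real[:n]


# ---------------------------------------------------------------------------
# single-recording profile
# ---------------------------------------------------------------------------

@dataclass
class EEGProfile:
    """Generative targets for one synthetic recording.

    Parameters
    ----------
    band_powers : dict
        Target in-band variance (uV^2) per band, *including* the aperiodic
        background's in-band contribution.
    aperiodic_exponent, aperiodic_offset : float
        Slope alpha >= 0 and log10(uV^2/Hz) intercept at 1 Hz of the 1/f
        background.
    asymmetry : float in [0, 1)
        Right-hemisphere amplitude gain knob (0 = symmetric).
    envelope_hurst : float in (0, 1)
        Hurst exponent of the band-envelope fGn.
    variability : float >= 0
        Envelope modulation depth ``m``; the realized MAD/median of 10-s
        band power increases monotonically with it.
    """

    n_channels: int = 19
    fs: float = 256.0
    duration: float = 600.0
    aperiodic_exponent: float = 1.5
    #: log10(uV^2/Hz) at 1 Hz; the default keeps oscillation peaks within a
    #: realistic factor of the background so the 1/f fit stays identifiable
    aperiodic_offset: float = 1.2
    # beta overlaps alpha (10-20 vs 8-13 Hz), so its default must exceed the
    # alpha spill into 10-13 Hz for the targets to be jointly realizable
    band_powers: dict = field(
        default_factory=lambda: {"delta": 120.0, "theta": 40.0, "alpha": 80.0, "beta": 60.0}
    )
    asymmetry: float = 0.0
    envelope_hurst: float = 0.7
    variability: float = 0.35
    seed: int = 0
    labels: "tuple[str, ...] | None" = None

    def __post_init__(self) -> None:
        if self.labels is None:
            if self.n_channels != len(STANDARD_1020):
                raise ValueError("labels must be given for a non-19-channel montage")
            self.labels = STANDARD_1020
        if len(self.labels) != self.n_channels:
            raise ValueError("labels length must match n_channels")
        if not 0.0 <= self.asymmetry < 1.0:
            raise ValueError("asymmetry must be in [0, 1)")
        if not 0.0 < self.envelope_hurst < 1.0:
            raise ValueError("envelope_hurst must be in (0, 1)")
        if self.aperiodic_exponent < 0:
            raise ValueError("aperiodic exponent must be >= 0")
        if any(p < 0 for p in self.band_powers.values()):
            raise ValueError("band powers must be >= 0")
        hi = max(h for _, h in BANDS.values())
        if self.fs <= 2 * hi:
            raise ValueError(f"fs must exceed twice the highest band edge ({hi} Hz)")
        if self.duration < 60.0:
            raise ValueError("duration must be >= 60 s to support envelope estimation")


def _background_psd(freqs: np.ndarray, offset: float, exponent: float) -> np.ndarray:
    """One-sided aperiodic PSD model (uV^2/Hz), flattened below 0.5 Hz."""
    f = np.maximum(freqs, 0.5)
    return 10.0**offset * f ** (-exponent)


def _background_band_power(offset: float, exponent: float, lo: float, hi: float) -> float:
    """Analytic integral of the aperiodic PSD over [lo, hi]."""
    a = 10.0**offset
    if abs(exponent - 1.0) < 1e-12:
        return a * np.log(hi / lo)
    return a * (hi ** (1 - exponent) - lo ** (1 - exponent)) / (1 - exponent)


def generate_recording(
    profile: EEGProfile,
    t_after_trauma: float = float("nan"),
    mirror_hemispheres: bool = False,
) -> Recording:
    """Synthesize one multichannel recording from a profile.

    Parameters
    ----------
    mirror_hemispheres : bool
        If True, each right-hemisphere channel is an exact copy of its
        homologous left channel *before* the asymmetry gain is applied, so
        the realized brain symmetry index is determined by ``asymmetry``
        alone (exactly 0 when ``asymmetry`` is 0).
    """
    p = profile
    rng = np.random.default_rng(p.seed)
    n = int(round(p.duration * p.fs))
    freqs = sfft.rfftfreq(n, 1.0 / p.fs)

    def _shaped_noise(amplitude: np.ndarray) -> np.ndarray:
        """Gaussian noise with the given one-sided amplitude spectrum.

        Draws random phases only on the support of the shaping curve
        (single-precision; the synthesis is statistical, not numerical).
        """
        nz = np.flatnonzero(amplitude > amplitude.max() * 1e-7)
        spec = np.zeros((p.n_channels, freqs.size), dtype=np.complex64)
        draws = rng.standard_normal((p.n_channels, nz.size, 2), dtype=np.float32)
        spec[:, nz] = (draws[..., 0] + 1j * draws[..., 1]) * (
            amplitude[nz].astype(np.float32) / np.sqrt(2.0, dtype=np.float32))
        spec[:, 0] = 0.0
        spec[:, -1] = spec[:, -1].real * np.sqrt(2.0)
        return sfft.irfft(spec, n=n, axis=1)  # float32; cast at the end

    # aperiodic background by spectral shaping with random phases
    psd = _background_psd(freqs, p.aperiodic_offset, p.aperiodic_exponent)
    psd[0] = 0.0
    x = _shaped_noise(np.sqrt(psd * p.fs * n / 2.0))

    # Narrowband oscillations: constant-modulus, randomly frequency-modulated
    # carriers (independent phase per channel), amplitude-modulated by the
    # shared fGn-derived envelope.  Constant modulus makes the realized band
    # amplitude envelope equal the prescribed envelope, so its Hurst exponent
    # is carried through to the measured amplitude dynamics.
    band_list = list(BANDS)
    carriers, envelopes, env_msq, band_frac = {}, {}, {}, {}
    t_idx = np.arange(n, dtype=np.float32)
    for band, (lo, hi) in BANDS.items():
        f0, width = 0.5 * (lo + hi), hi - lo
        # slow frequency wander: Gaussian-lowpassed noise, SD width/4, so the
        # instantaneous frequency fills the band with compact spectral tails
        fm = max(width / 10.0, 0.05)
        g = _shaped_noise(np.exp(-((freqs / fm) ** 2)))
        g /= np.maximum(g.std(axis=1, keepdims=True), 1e-12)
        f_inst = f0 + (width / 4.0) * g
        phase0 = rng.uniform(0, 2 * np.pi, p.n_channels).astype(np.float32)
        theta = 2.0 * np.pi * np.cumsum(f_inst, axis=1, dtype=np.float32) / p.fs
        carriers[band] = np.cos(theta + phase0[:, None])
        del theta, f_inst, g
        z = generate_fgn(p.envelope_hurst, n, rng)
        env = np.clip(1.0 + p.variability * (z - z.mean()) / max(z.std(), 1e-12),
                      0.05, None).astype(np.float32)
        envelopes[band] = env
        env_msq[band] = float((env.astype(float) ** 2).mean())
        # per-band power fractions of this carrier (channel-0 periodogram)
        spec0 = sfft.rfft(carriers[band][0].astype(float))
        p0 = (spec0.real**2 + spec0.imag**2) * 2.0 / n**2
        band_frac[band] = {
            b: float(p0[(freqs >= BANDS[b][0]) & (freqs <= BANDS[b][1])].sum())
            for b in band_list
        }

    # The band scheme overlaps (alpha/beta) and carriers have tails, so
    # realized in-band power mixes contributions: solve a non-negative
    # least-squares system for the per-carrier weights that best realize the
    # targets on top of the aperiodic background.
    mix = np.array([[band_frac[src][tgt] for src in band_list]
                    for tgt in band_list])
    deficit = np.array([
        p.band_powers.get(b, 0.0)
        - _background_band_power(p.aperiodic_offset, p.aperiodic_exponent, *BANDS[b])
        for b in band_list
    ])
    from scipy.optimize import nnls

    weights, _ = nnls(mix, np.clip(deficit, 0.0, None))

    for band, w in zip(band_list, weights):
        if w <= 0:
            continue
        scale = np.float32(np.sqrt(w / env_msq[band]))
        x += (envelopes[band] * scale)[None, :] * carriers[band]
        del carriers[band]

    if mirror_hemispheres:
        for li, ri in homologous_indices(p.labels):
            x[ri] = x[li]
    if p.asymmetry > 0:
        gain = (1.0 + p.asymmetry) / (1.0 - p.asymmetry)
        x[right_indices(p.labels)] *= gain

    return Recording(samples=x, labels=list(p.labels), fs=p.fs,
                     t_after_trauma=t_after_trauma)


# ---------------------------------------------------------------------------
# artifact injection
# ---------------------------------------------------------------------------

def inject_artifacts(
    rec: Recording,
    kind: str,
    windows: "list[tuple[int, int]] | None" = None,
    channels: "list[int] | None" = None,
    window_s: float = 10.0,
    amplitude: float = 300.0,
    noise_sd: float = 45.0,
    seed: int = 0,
) -> Recording:
    """Return a copy of ``rec`` with controlled threshold violations.

    Parameters
    ----------
    kind : {"spike", "noise_burst", "flat_channel"}
        ``spike`` adds a smooth 80-ms Gaussian deflection peaking at
        ``amplitude`` uV in each requested (channel, window) — an
        electrode-pop analogue whose spectral content survives the 0.1-40-Hz
        analysis band-pass; ``noise_burst`` replaces each requested window
        with 2-30-Hz band-limited noise of SD ``noise_sd`` uV clipped to
        +-195 uV (high variance without tripping the amplitude rule);
        ``flat_channel`` zeroes the requested channels.
    windows : list of (channel_index, window_index)
        Required for spike/noise_burst.
    channels : list of channel indices
        Required for flat_channel.
    """
    from scipy import signal as sps

    out = rec.copy()
    w = int(round(window_s * rec.fs))
    rng = np.random.default_rng(seed)
    if kind == "flat_channel":
        if not channels:
            raise ValueError("flat_channel needs channel indices")
        for ch in channels:
            out.samples[ch] = 0.0
        return out
    if not windows:
        raise ValueError(f"{kind} needs (channel, window) pairs")
    for ch, wi in windows:
        sl = slice(wi * w, (wi + 1) * w)
        if sl.stop > rec.n_times:
            raise ValueError(f"window {wi} outside recording")
        if kind == "spike":
            sigma = 0.04 * rec.fs  # ~80 ms full width: in-band deflection
            t = np.arange(w, dtype=float)
            out.samples[ch, sl] += amplitude * np.exp(
                -((t - w // 2) ** 2) / (2.0 * sigma**2))
        elif kind == "noise_burst":
            sos = sps.butter(4, (2.0, 30.0), btype="bandpass", fs=rec.fs,
                             output="sos")
            burst = sps.sosfiltfilt(sos, rng.standard_normal(w))
            burst *= noise_sd / burst.std()
            out.samples[ch, sl] = np.clip(burst, -195, 195)
        else:
            raise ValueError(f"unknown artifact kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CovariateSpec:
    """Distribution and outcome coupling of one clinical covariate.

    ``kind`` is ``"normal"`` (mean, sd, clipped to ``bounds``),
    ``"categorical"`` (integer levels with probabilities) or ``"bernoulli"``.
    ``log_odds`` is the poor-outcome log-odds per standard deviation of the
    covariate (standardized over the cohort draw).
    """

    kind: str
    params: tuple
    log_odds: float
    bounds: "tuple[float, float] | None" = None


#: Admission covariates of the IMPACT prognostic model, with plausible ICU
#: distributions and outcome couplings used only for synthetic cohorts.
DEFAULT_COVARIATE_MODEL: dict[str, CovariateSpec] = {
    "age": CovariateSpec("normal", (50.0, 16.0), 0.9, (16.0, 92.0)),
    "motor_score": CovariateSpec(
        "categorical", ((1, 2, 3, 4, 5, 6), (0.12, 0.13, 0.15, 0.2, 0.25, 0.15)), -0.6
    ),
    "pupils": CovariateSpec("categorical", ((0, 1, 2), (0.7, 0.15, 0.15)), 0.7),
    "hypoxia": CovariateSpec("bernoulli", (0.2,), 0.3),
    "hypotension": CovariateSpec("bernoulli", (0.25,), 0.3),
    "ct_class": CovariateSpec(
        "categorical", ((1, 2, 3, 4, 5, 6), (0.1, 0.3, 0.2, 0.1, 0.15, 0.15)), 0.5
    ),
    "tsah": CovariateSpec("bernoulli", (0.45,), 0.25),
    "epidural_hematoma": CovariateSpec("bernoulli", (0.15,), -0.1),
    "glucose": CovariateSpec("normal", (8.0, 2.5), 0.4, (2.5, 25.0)),
    "hemoglobin": CovariateSpec("normal", (8.5, 1.3), -0.4, (4.0, 12.0)),
}

#: Standardized EEG-profile shifts of the poor-outcome class (in units of the
#: between-patient SD of each knob).  Signs follow the clinical direction:
#: poor outcome shows lower alpha power, more delta, more asymmetry, less
#: alpha-power variability.
DEFAULT_EFFECT_SIZES: dict[str, float] = {
    "alpha_power": 1.0,
    "delta_power": 1.0,
    "asymmetry": 1.0,
    "variability": 1.0,
}

#: Between-patient SD of each profile knob (log-space for band powers).
_PROFILE_SD = {
    "log_band_power": 0.3,
    "asymmetry": 0.08,
    "variability": 0.10,
    "envelope_hurst": 0.04,
    "aperiodic_exponent": 0.25,
    "aperiodic_offset": 0.15,
}


@dataclass
class CohortSpec:
    """Specification of a synthetic patient cohort."""

    n_patients: int = 60
    p_poor: float = 0.5
    effect_sizes: dict = field(default_factory=lambda: dict(DEFAULT_EFFECT_SIZES))
    timepoints: tuple = (12.0, 24.0, 48.0, 72.0, 96.0)
    covariate_model: dict = field(default_factory=lambda: dict(DEFAULT_COVARIATE_MODEL))
    duration: float = 1800.0
    #: timepoints at which the outcome effects apply (None = all); lets a
    #: cohort carry prognostic signal only late after trauma
    effect_timepoints: "tuple | None" = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.p_poor < 1.0:
            raise ValueError("p_poor must be in (0, 1)")
        if self.n_patients < 4:
            raise ValueError("need at least 2 patients per class")


@dataclass
class Cohort:
    """Synthetic cohort: clinical table plus lazily-built recordings.

    ``table`` has one row per patient: ``patient_id``, ``outcome`` (1 = poor,
    GOSE 1-3 analogue) and the IMPACT covariates.  Recordings are synthesized
    on demand from stored per-(patient, timepoint) profiles to keep memory
    bounded.
    """

    table: pd.DataFrame
    profiles: dict
    timepoints: tuple

    def recording(self, patient_id: str, timepoint: float,
                  mirror_hemispheres: bool = False) -> Recording:
        profile = self.profiles[(patient_id, timepoint)]
        # centre the recording on the monitoring timepoint
        start = timepoint - profile.duration / 7200.0
        return generate_recording(profile, t_after_trauma=start,
                                  mirror_hemispheres=mirror_hemispheres)

    def iter_recordings(self, timepoints: "tuple | None" = None
                        ) -> Iterator[tuple[str, float, Recording]]:
        for pid in self.table["patient_id"]:
            for tp in timepoints or self.timepoints:
                yield pid, tp, self.recording(pid, tp)


def _draw_covariates(model: dict, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for name, cv in model.items():
        if cv.kind == "normal":
            mu, sd = cv.params
            v = rng.normal(mu, sd, n)
            if cv.bounds:
                v = np.clip(v, *cv.bounds)
        elif cv.kind == "categorical":
            levels, probs = cv.params
            v = rng.choice(levels, size=n, p=probs).astype(float)
        elif cv.kind == "bernoulli":
            v = (rng.random(n) < cv.params[0]).astype(float)
        else:
            raise ValueError(f"unknown covariate kind {cv.kind!r}")
        cols[name] = v
    return pd.DataFrame(cols)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a synthetic cohort of patients with outcome-coupled EEG profiles.

    Covariates are drawn first; the poor-outcome label follows a logistic
    model over their standardized values with the intercept calibrated so
    the expected poor-outcome fraction equals ``p_poor``.  The EEG profile of
    each poor-outcome patient is then shifted by ``effect_sizes`` (in units
    of the between-patient SD of each knob): lower alpha power, higher delta
    power, higher asymmetry, lower envelope variability.

    Everything is a deterministic function of ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    cov = _draw_covariates(spec.covariate_model, n, rng)

    lin = np.zeros(n)
    for name, cv in spec.covariate_model.items():
        v = cov[name].to_numpy()
        sd = v.std()
        if sd > 0:
            lin += cv.log_odds * (v - v.mean()) / sd
    # intercept calibrated so that mean sigmoid(lin + c) = p_poor
    from scipy.optimize import brentq

    def excess(c: float) -> float:
        return float(np.mean(1.0 / (1.0 + np.exp(-(lin + c)))) - spec.p_poor)

    c = brentq(excess, -30.0, 30.0)
    outcome = (rng.random(n) < 1.0 / (1.0 + np.exp(-(lin + c)))).astype(int)
    # honour the >= 2 patients per class contract
    while outcome.sum() < 2:
        outcome[int(rng.integers(n))] = 1
    while (1 - outcome).sum() < 2:
        outcome[int(rng.integers(n))] = 0

    table = cov.copy()
    table.insert(0, "patient_id", [f"P{i:03d}" for i in range(n)])
    table.insert(1, "outcome", outcome)

    es = dict(spec.effect_sizes)
    base = EEGProfile()
    profiles: dict = {}
    sd = _PROFILE_SD
    for i in range(n):
        poor = bool(outcome[i])
        # patient-level knob draws
        log_bp = {b: np.log(v) + rng.normal(0, sd["log_band_power"])
                  for b, v in base.band_powers.items()}
        asym = float(np.clip(rng.normal(0.08, sd["asymmetry"]), 0.0, 0.9))
        var = float(np.clip(rng.normal(base.variability, sd["variability"]), 0.05, 1.0))
        hurst = float(np.clip(rng.normal(base.envelope_hurst, sd["envelope_hurst"]),
                              0.55, 0.95))
        expo = float(np.clip(rng.normal(base.aperiodic_exponent,
                                        sd["aperiodic_exponent"]), 0.3, 3.0))
        off = float(rng.normal(base.aperiodic_offset, sd["aperiodic_offset"]))
        for tp in spec.timepoints:
            log_bp_tp, asym_tp, var_tp = dict(log_bp), asym, var
            affected = (spec.effect_timepoints is None
                        or tp in spec.effect_timepoints)
            if poor and affected:
                log_bp_tp["alpha"] -= es.get("alpha_power", 0.0) * sd["log_band_power"]
                log_bp_tp["delta"] += es.get("delta_power", 0.0) * sd["log_band_power"]
                asym_tp = float(np.clip(
                    asym + es.get("asymmetry", 0.0) * sd["asymmetry"], 0.0, 0.9))
                var_tp = float(np.clip(
                    var - es.get("variability", 0.0) * sd["variability"], 0.05, 1.0))
            jitter = rng.normal(0, 0.05, len(log_bp_tp))
            bp = {b: float(np.exp(lv + j))
                  for (b, lv), j in zip(log_bp_tp.items(), jitter)}
            profiles[(f"P{i:03d}", tp)] = EEGProfile(
                duration=spec.duration,
                band_powers=bp,
                asymmetry=asym_tp,
                variability=var_tp,
                envelope_hurst=hurst,
                aperiodic_exponent=expo,
                aperiodic_offset=off,
                seed=int(rng.integers(2**31)),
            )
    return Cohort(table=table, profiles=profiles, timepoints=tuple(spec.timepoints))


def export_cohort(cohort: Cohort, out_dir, timepoints: "tuple | None" = None) -> None:
    """Write the cohort to disk: one EDF per (patient, timepoint) plus
    ``cohort.csv`` with labels and IMPACT covariates."""
    from pathlib import Path

    from .io import write_edf

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(out / "cohort.csv", index=False)
    for pid, tp, rec in cohort.iter_recordings(timepoints):
        write_edf(rec, out / f"{pid}_t{int(tp):03d}h.edf")
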