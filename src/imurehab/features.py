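"""The 352-feature repetition representation.

For each of the nine signal vectors (accel x/y/z, gyro x/y/z, acceleration
magnitude, pitch, roll) a repetition yields 14 static time-domain features
and 25 dynamic frequency-domain features; the Pearson correlation between
pitch and roll closes the set: 9 x 39 + 1 = 352.

Dynamic features are computed on the repetition resampled to a fixed
length (default 256) so that "the first 20 Fourier coefficients" index the
same normalized frequencies for every repetition regardless of its
duration.  The energy-style summaries (energy, energy ratio, energy
average, harmonic ratio, energy entropy) are conventions of this package,
each isolated in one function so alternates can be swapped:

- energy: mean-removed average power of the resampled segment, computed
  from the one-sided spectrum with Parseval weights (equals the population
  variance exactly).
- energy ratio: share of non-DC spectral power in the lower half-band.
- energy average: energy divided by the number of non-DC one-sided bins.
- harmonic ratio: share of non-DC spectral power in the single strongest bin.
- energy entropy: Shannon entropy (bits) of the normalized non-DC power
  spectrum.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .io import DerivedSignals, Repetition, ValidationError

DEFAULT_FFT_LENGTH = 256

STATIC_NAMES = (
    "mean", "median", "std", "var", "range", "kurtosis", "skewness",
    "max", "min", "pos_mean", "neg_mean", "sad", "q1", "q3",
)

DYNAMIC_NAMES = (
    "energy", "energy_ratio", "energy_avg", "harmonic_ratio", "energy_entropy",
) + tuple(f"fft_{k:02d}" for k in range(1, 21))

VECTOR_NAMES = DerivedSignals.NAMES

#: Canonical ordering of all 352 feature names.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{vec}.{feat}"
    for vec in VECTOR_NAMES
    for feat in STATIC_NAMES + DYNAMIC_NAMES
) + ("corr.pitch_roll",)

N_FEATURES = len(FEATURE_NAMES)
assert N_FEATURES == 352


def static_features(v: np.ndarray) -> np.ndarray:
    """The 14 static time-domain features of one signal vector.

    SD/variance are population (ddof=0); skewness and excess kurtosis are
    the biased moment estimators, defined as 0 for a zero-variance input;
    positive/negative means are 0 when the respective subset is empty;
    quartiles use linear interpolation.
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or len(v) < 4:
        raise ValidationError("static features need a 1-D vector of length >= 4")
    sd = float(np.std(v))
    if sd == 0.0:
        kurt, skew = 0.0, 0.0
    else:
        kurt = float(stats.kurtosis(v, fisher=True, bias=True))
        skew = float(stats.skew(v, bias=True))
    pos = v[v > 0]
    neg = v[v < 0]
    q1, q3 = np.percentile(v, [25.0, 75.0])
    return np.array([
        float(np.mean(v)),
        float(np.median(v)),
        sd,
        sd**2,
        float(np.max(v) - np.min(v)),
        kurt,
        skew,
        float(np.max(v)),
        float(np.min(v)),
        float(np.mean(pos)) if len(pos) else 0.0,
        float(np.mean(neg)) if len(neg) else 0.0,
        float(np.sum(np.abs(np.diff(v)))),
        float(q1),
        float(q3),
    ])


def _resample(v: np.ndarray, length: int) -> np.ndarray:
    src = np.linspace(0.0, 1.0, len(v))
    dst = np.linspace(0.0, 1.0, length)
    return np.interp(dst, src, v)


def spectral_energy(m: np.ndarray, n: int) -> float:
    """Mean-removed average power from one-sided magnitudes ``m`` of an
    n-point real DFT (Parseval weights: interior bins doubled)."""
    p = m**2
    total = 2.0 * np.sum(p[1:-1]) + p[-1] if n % 2 == 0 else 2.0 * np.sum(p[1:])
    return float(total) / n**2


def energy_ratio(m: np.ndarray) -> float:
    """Lower-half band share of non-DC spectral power."""
    p = m[1:] ** 2
    total = np.sum(p)
    if total == 0.0:
        return 0.0
    half = len(m) // 2  # bins 1 .. K/2 of the one-sided spectrum
    return float(np.sum(m[1:half + 1] ** 2) / total)


def harmonic_ratio(m: np.ndarray) -> float:
    """Share of non-DC spectral power held by the strongest bin."""
    p = m[1:] ** 2
    total = np.sum(p)
    if total == 0.0:
        return 0.0
    return float(np.max(p) / total)


def energy_entropy(m: np.ndarray) -> float:
    """Shannon entropy (bits) of the normalized non-DC power spectrum."""
    p = m[1:] ** 2
    total = np.sum(p)
    if total == 0.0:
        return 0.0
    p = p / total
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def dynamic_features(v: np.ndarray, fixed_length: int = DEFAULT_FFT_LENGTH) -> np.ndarray:
    """The 25 dynamic frequency-domain features of one signal vector.

    The vector is resampled to ``fixed_length``, transformed by a one-sided
    real DFT, and summarized by five energy-style statistics plus the first
    20 non-DC magnitude coefficients.  A zero-variance segment yields all
    zeros (DC is excluded throughout).
    """
    v = np.asarray(v, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValidationError("dynamic features need a 1-D vector of length >= 2")
    y = _resample(v, fixed_length)
    m = np.abs(np.fft.rfft(y))
    k_nondc = len(m) - 1
    coeffs = m[1:21]
    if len(coeffs) < 20:  # pragma: no cover - fixed_length >= 40 in practice
        coeffs = np.pad(coeffs, (0, 20 - len(coeffs)))
    e = spectral_energy(m, fixed_length)
    return np.concatenate([
        [e, energy_ratio(m), e / k_nondc, harmonic_ratio(m), energy_entropy(m)],
        coeffs,
    ])


def pitch_roll_correlation(pitch: np.ndarray, roll: np.ndarray) -> float:
    """Pearson r between pitch and roll; 0 if either vector is constant."""
    if np.std(pitch) == 0.0 or np.std(roll) == 0.0:
        return 0.0
    return float(np.corrcoef(pitch, roll)[0, 1])


def extract_features(
    sig: DerivedSignals,
    rep: Repetition,
    fixed_length: int = DEFAULT_FFT_LENGTH,
) -> np.ndarray:
    """The full 352-value feature vector of one repetition.

    Values follow :data:`FEATURE_NAMES` order: for each of the nine signal
    vectors the 14 static then 25 dynamic features, closed by the
    pitch-roll Pearson correlation.
    """
    if rep.end > sig.n_samples:
        raise ValidationError("repetition bounds exceed the signal")
    if rep.n_samples < 4:
        raise ValidationError("repetition must span at least 4 samples")
    sl = slice(rep.start, rep.end)
    blocks = []
    for name in VECTOR_NAMES:
        v = sig.vector(name)[sl]
        blocks.append(static_features(v))
        blocks.append(dynamic_features(v, fixed_length))
    blocks.append([pitch_roll_correlation(sig.pitch[sl], sig.roll[sl])])
    out = np.concatenate(blocks)
    if out.shape[0] != N_FEATURES:  # pragma: no cover - structural guarantee
        raise RuntimeError("feature count mismatch")
    return out


def feature_matrix(
    sig: DerivedSignals, reps, fixed_length: int = DEFAULT_FFT_LENGTH
) -> np.ndarray:
    """Stack :func:`extract_features` over an iterable of repetitions."""
    return np.stack([extract_features(sig, r, fixed_length) for r in reps])
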