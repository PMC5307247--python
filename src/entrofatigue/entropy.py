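"""The four entropy features: sample, fuzzy, approximate and spectral entropy.

All four quantify the regularity/complexity of a short EEG epoch and decrease
when the signal becomes more predictable — the premise of entropy-based
fatigue detection.  The template-matching entropies (AE, SE, FE) share the
embedding dimension ``m`` (default 2) and tolerance ``r = r_factor * SD`` of
the analyzed series (default 0.2), with the Chebyshev (max-norm) template
distance throughout:

* **Approximate entropy (AE)** — Pincus: ``Phi^m(r) - Phi^(m+1)(r)`` with
  self-matches included, hence always finite but biased.
* **Sample entropy (SE)** — Richman & Moorman: ``-ln(A/B)`` over template
  pairs, self-matches excluded; ``A = B = 0`` is possible on very regular
  short series, handled by an ``inf`` sentinel (imputed downstream).
* **Fuzzy entropy (FE)** — Chen et al.: templates are baseline-removed and
  the hard threshold is replaced by the membership ``exp(-(d/r)^n)``,
  giving a strictly positive, noise-robust match degree.
* **Spectral entropy (PE)** — Shannon entropy of the normalized in-band power
  spectrum of the epoch (Welch average of rectangular-window segments),
  optionally divided by ``ln(K)`` so it lies in [0, 1].

Implementations are vectorized (O(N^2) pairwise distance matrices); the
module :mod:`entrofatigue.reference` holds deliberately naive double-loop
versions used as oracles in the test-suite.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy.signal import welch
from scipy.spatial.distance import cdist

from .preprocess import EpochSet

logger = logging.getLogger(__name__)

FEATURE_NAMES = ("SE", "FE", "AE", "PE")


class DegenerateSignalError(ValueError):
    """Raised when a series has zero variance (tolerance r would be 0)."""


@dataclass(frozen=True)
class EntropyParams:
    """Shared parameters of the entropy estimators.

    m : embedding dimension (template length) for AE/SE/FE.
    r_factor : tolerance multiplier; r = r_factor * SD of the analyzed epoch.
    fuzzy_n : exponent of the fuzzy membership function exp(-(d/r)^n).
    pe_band : (low, high) Hz band retained for spectral entropy.
    pe_normalize : divide the spectral entropy by ln(K) (K = retained bins).
    """

    m: int = 2
    r_factor: float = 0.2
    fuzzy_n: float = 2.0
    pe_band: tuple[float, float] = (0.5, 45.0)
    pe_normalize: bool = True

    def __post_init__(self) -> None:
        if self.m < 1:
            raise ValueError("m must be >= 1")
        if self.r_factor <= 0:
            raise ValueError("r_factor must be > 0")
        if self.fuzzy_n < 1:
            raise ValueError("fuzzy_n must be >= 1")
        lo, hi = self.pe_band
        if not 0 < lo < hi:
            raise ValueError("pe_band must satisfy 0 < low < high")


def _tolerance(x: np.ndarray, p: EntropyParams) -> float:
    sd = float(np.std(x))  # population SD of the analyzed epoch
    if sd == 0.0:
        raise DegenerateSignalError("constant series: SD = 0, tolerance r = 0")
    return p.r_factor * sd


def _check_length(x: np.ndarray, p: EntropyParams) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if x.size < p.m + 2:
        raise ValueError(f"series of length {x.size} too short for m={p.m}")
    return x


def approximate_entropy(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Approximate entropy (Pincus), self-matches included.

    ``Phi^m(r)`` is the mean log fraction of templates within Chebyshev
    distance ``r`` of each length-``m`` template (the template itself
    counts, so the fraction is never 0 and the value is always finite).
    """
    p = p or EntropyParams()
    x = _check_length(x, p)
    r = _tolerance(x, p)

    def phi(mm: int) -> float:
        templates = sliding_window_view(x, mm)
        d = cdist(templates, templates, metric="chebyshev")
        frac = (d <= r).mean(axis=1)
        return float(np.mean(np.log(frac)))

    return phi(p.m) - phi(p.m + 1)


def sample_entropy(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Sample entropy (Richman & Moorman), self-matches excluded.

    Both template lengths use the same ``N - m`` starting indices so that
    ``A <= B``.  Returns ``inf`` (with a warning) when no length-``m+1``
    match exists; callers impute the sentinel (see
    :func:`extract_features`).
    """
    p = p or EntropyParams()
    x = _check_length(x, p)
    r = _tolerance(x, p)
    n_templates = x.size - p.m

    t_m = sliding_window_view(x, p.m)[:n_templates]
    t_m1 = sliding_window_view(x, p.m + 1)

    def pair_count(templates: np.ndarray) -> int:
        d = cdist(templates, templates, metric="chebyshev")
        within = (d <= r).sum() - len(templates)  # drop self-matches
        return int(within) // 2

    b = pair_count(t_m)
    a = pair_count(t_m1)
    if b == 0 or a == 0:
        warnings.warn("sample_entropy: no template matches (A or B = 0); returning inf",
                      stacklevel=2)
        return float("inf")
    return float(-np.log(a / b))


def fuzzy_entropy(x: np.ndarray, p: EntropyParams | None = None) -> float:
    """Fuzzy entropy (Chen et al.): soft template matching.

    Templates are baseline-removed (their own mean subtracted) and the
    similarity of a pair is ``exp(-(d/r)^n)`` with ``d`` the Chebyshev
    distance.  The match degree is strictly positive, so the value is always
    finite for non-constant input, and it is invariant to adding a constant
    offset to the series.
    """
    p = p or EntropyParams()
    x = _check_length(x, p)
    r = _tolerance(x, p)
    n_templates = x.size - p.m

    def phi(mm: int) -> float:
        templates = sliding_window_view(x, mm)[:n_templates].astype(float)
        templates = templates - templates.mean(axis=1, keepdims=True)
        d = cdist(templates, templates, metric="chebyshev")
        sim = np.exp(-((d / r) ** p.fuzzy_n))
        total = sim.sum() - n_templates  # remove i == j terms (similarity 1)
        return total / (n_templates * (n_templates - 1))

    return float(np.log(phi(p.m)) - np.log(phi(p.m + 1)))


def spectral_entropy(x: np.ndarray, fs: float, p: EntropyParams | None = None) -> float:
    """Shannon entropy of the normalized in-band power spectrum.

    The spectrum is a Welch estimate over rectangular-window segments of a
    fifth of the epoch (50% overlap, mean removed per segment) — for a 1-s
    epoch that is a 5 Hz bin width, ~9 averaged segments.  A single
    full-length periodogram would be an (asymptotically) unbiased but very
    noisy spectrum whose sampling fluctuations depress the entropy of
    broadband signals well below the flat-spectrum limit; segment averaging
    restores it.  The rectangular window keeps a tone at a bin frequency
    concentrated in a single bin, so narrow-band signals stay near entropy 0.
    Bins inside ``pe_band`` are normalized to a probability vector whose
    Shannon entropy (natural log) is returned, divided by ``ln(K)`` when
    ``pe_normalize`` so the result lies in [0, 1].
    """
    p = p or EntropyParams()
    x = np.asarray(x, dtype=float).ravel()
    if x.size < 64:
        raise ValueError("spectral entropy needs at least 64 samples")
    if np.all(x == 0):
        raise DegenerateSignalError("all-zero signal has no power spectrum")
    lo, hi = p.pe_band
    if hi >= fs / 2.0 + 1e-12:
        # tolerate hi == Nyquist; reject beyond
        if hi > fs / 2.0:
            raise ValueError(f"pe_band upper edge {hi} Hz exceeds Nyquist {fs / 2} Hz")
    freqs, power = welch(x, fs=fs, window="boxcar", nperseg=x.size // 5,
                         detrend="constant")
    mask = (freqs >= lo) & (freqs <= hi)
    k = int(mask.sum())
    if k < 2:
        raise ValueError(f"pe_band [{lo}, {hi}] Hz contains {k} < 2 spectral bins")
    band = power[mask]
    total = band.sum()
    if total == 0:
        raise DegenerateSignalError("no in-band power")
    prob = band / total
    nz = prob[prob > 0]
    h = float(-(nz * np.log(nz)).sum())
    return h / np.log(k) if p.pe_normalize else h


_FEATURE_FUNCS = {
    "AE": lambda x, fs, p: approximate_entropy(x, p),
    "SE": lambda x, fs, p: sample_entropy(x, p),
    "FE": lambda x, fs, p: fuzzy_entropy(x, p),
    "PE": lambda x, fs, p: spectral_entropy(x, fs, p),
}

#: fraction of degenerate (zero-variance) epochs tolerated as missing values
MAX_DEGENERATE_FRACTION = 0.001


def extract_features(epochs: EpochSet,
                     features: tuple[str, ...] = FEATURE_NAMES,
                     p: EntropyParams | None = None) -> pd.DataFrame:
    """Compute the requested entropy features for every epoch.

    Returns a tidy table with columns ``subject``, ``channel``, ``epoch``,
    ``label``, ``feature``, ``value``.  The tolerance ``r`` is computed
    per epoch from that epoch's SD.  Policy for pathological epochs:

    * ``inf`` sample-entropy sentinels (no template match) are replaced by
      the largest finite value of the same feature column; the count is
      logged.
    * zero-variance epochs yield missing values; if they exceed
      ``MAX_DEGENERATE_FRACTION`` of the epochs the extraction aborts.
    """
    p = p or EntropyParams()
    unknown = set(features) - set(FEATURE_NAMES)
    if unknown:
        raise ValueError(f"unknown features {sorted(unknown)}; valid: {FEATURE_NAMES}")

    rows: list[tuple] = []
    n_degenerate = 0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # sentinel warnings are aggregated below
        for feat in features:
            func = _FEATURE_FUNCS[feat]
            for i in range(epochs.n_epochs):
                try:
                    value = func(epochs.epochs[i], epochs.fs, p)
                except DegenerateSignalError:
                    value = np.nan
                    n_degenerate += 1
                rows.append((epochs.subject_id, epochs.channel, i,
                             int(epochs.labels[i]), feat, value))

    table = pd.DataFrame(rows, columns=["subject", "channel", "epoch",
                                        "label", "feature", "value"])
    total = len(features) * epochs.n_epochs
    if n_degenerate > MAX_DEGENERATE_FRACTION * total:
        raise DegenerateSignalError(
            f"{n_degenerate}/{total} epochs degenerate (> {MAX_DEGENERATE_FRACTION:.1%})")

    n_inf = int(np.isinf(table["value"]).sum())
    if n_inf:
        logger.warning("extract_features: imputing %d inf sample-entropy sentinel(s) "
                       "with the column maximum", n_inf)
        for feat in features:
            mask = table["feature"] == feat
            col = table.loc[mask, "value"]
            inf_mask = np.isinf(col)
            if inf_mask.any():
                if inf_mask.all():
                    raise DegenerateSignalError(
                        f"feature {feat}: every epoch hit the no-match sentinel; "
                        "epochs are too short or too regular for m and r")
                finite_max = col[~inf_mask].max()
                table.loc[mask & np.isinf(table["value"]), "value"] = finite_max
    return table
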