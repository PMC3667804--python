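"""Homotopic ROI timecourses, amplitude spectra, and their correlation.

Reproduces the classic demonstration of interhemispheric LFF synchrony: the
percentage-signal-change timecourses of a seed ROI and its mirror-image
partner, their one-sided Fourier amplitude spectra, and the lag-0 Pearson
correlation between them.  Spectra use a plain rectangular window (raw
transforms) and an energy-preserving normalization, so that the sum of
squared amplitudes equals the time-domain energy (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError

__all__ = [
    "SpectrumResult",
    "percent_signal_change",
    "amplitude_spectrum",
    "homotopic_correlation",
    "plot_homotopic_pair",
]


@dataclass
class SpectrumResult:
    """One-sided discrete Fourier amplitude spectrum.

    ``amplitudes[k]`` is scaled so that ``sum(amplitudes**2) ==
    sum(x**2)`` (root-energy units); frequencies run from 0 to Nyquist with
    spacing ``1 / (n * TR)``.
    """

    frequencies: np.ndarray
    amplitudes: np.ndarray
    source: str = ""

    def energy(self) -> float:
        return float(np.sum(self.amplitudes**2))


def percent_signal_change(timecourse: np.ndarray) -> np.ndarray:
    """``100 * (x - mean) / mean``; requires a nonzero temporal mean."""
    x = np.asarray(timecourse, dtype=np.float64)
    m = x.mean()
    if m == 0:
        raise DegenerateInputError(
            "timecourse has zero temporal mean; percent signal change is undefined"
        )
    return 100.0 * (x - m) / m


def amplitude_spectrum(timecourse: np.ndarray, tr_s: float, source: str = "") -> SpectrumResult:
    """One-sided amplitude spectrum of a real timecourse.

    Energy-preserving scaling: interior bins carry weight sqrt(2/n), the DC
    and (for even n) Nyquist bins sqrt(1/n), so Parseval's identity holds
    exactly between ``amplitudes**2`` and the time-domain energy.
    """
    x = np.asarray(timecourse, dtype=np.float64)
    if x.ndim != 1 or x.size < 4:
        raise ParameterError("need a 1D timecourse with >= 4 points")
    if tr_s <= 0:
        raise ParameterError("tr_s must be positive")
    n = x.size
    spectrum = np.fft.rfft(x)
    weights = np.full(spectrum.size, 2.0 / n)
    weights[0] = 1.0 / n
    if n % 2 == 0:
        weights[-1] = 1.0 / n
    amplitudes = np.abs(spectrum) * np.sqrt(weights)
    return SpectrumResult(
        frequencies=np.fft.rfftfreq(n, d=tr_s), amplitudes=amplitudes, source=source
    )


def plot_homotopic_pair(bundle: dict, tr_s: float, path):
    """Two-panel figure: homotopic percent-signal traces and their spectra.

    ``bundle`` is the dict produced by the pipeline's homotopic-trace
    extraction (keys ``left``, ``right``, ``spectrum_left``,
    ``spectrum_right``, ``r``, ``region``, ``condition``).  Writes the
    figure to ``path`` and returns it.
    """
    from matplotlib.figure import Figure

    fig = Figure(figsize=(9, 3.2))
    ax_t, ax_f = fig.subplots(1, 2)
    t = np.arange(len(bundle["left"])) * tr_s
    ax_t.plot(t, bundle["left"], color="tab:blue", label="left")
    ax_t.plot(t, bundle["right"], color="tab:red", label="right")
    ax_t.set_xlabel("time (s)")
    ax_t.set_ylabel("signal fluctuation (%)")
    ax_t.set_title(f"{bundle.get('region', '')} {bundle.get('condition', '')} "
                   f"(r = {bundle['r']:.2f})")
    ax_t.legend(frameon=False)
    for side, color in (("left", "tab:blue"), ("right", "tab:red")):
        spec = bundle[f"spectrum_{side}"]
        ax_f.plot(spec.frequencies, spec.amplitudes, color=color)
    ax_f.set_xlabel("frequency (Hz)")
    ax_f.set_ylabel("amplitude")
    ax_f.set_title("Fourier transform")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    return path


def homotopic_correlation(left_tc: np.ndarray, right_tc: np.ndarray) -> float:
    """Lag-0 Pearson correlation between homotopic ROI-mean timecourses."""
    left = np.asarray(left_tc, dtype=np.float64)
    right = np.asarray(right_tc, dtype=np.float64)
    if left.shape != right.shape or left.ndim != 1:
        raise ParameterError("timecourses must be 1D and of equal length")
    if np.ptp(left) == 0 or np.ptp(right) == 0:
        raise DegenerateInputError("both timecourses must have nonzero variance")
    return float(stats.pearsonr(left, right).statistic)
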