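"""Homotopic timecourses and Fourier spectra (interhemispheric synchrony).

For one preoperative and one day-1 run, extracts the percent-signal-change
timecourses of the left-SI seed and its mirror-image right-SI partner after
full preprocessing, their one-sided amplitude spectra, and the lag-0 Pearson
correlation between hemispheres.  Preoperatively the pair is strongly
correlated with all spectral power below 0.08 Hz; on day 1 the correlation
drops to chance level.
"""

import numpy as np

from lffconn import SyntheticConfig, simulate_run
from lffconn.io import default_seeds
from lffconn.pipeline import _homotopic_traces
from lffconn.preprocess import PreprocessSpec

config = SyntheticConfig.reduced((48, 48, 10))
roi = default_seeds()["SI_L"]

for condition in ("preop", "d1"):
    run, _ = simulate_run(config, condition, np.random.default_rng(21), "rat01")
    bundle = _homotopic_traces(run, roi, PreprocessSpec(), "rat01")
    spec = bundle["spectrum_left"]
    peak = spec.frequencies[np.argmax(spec.amplitudes)]
    above_band = spec.amplitudes[spec.frequencies > 0.08 + 1e-12].max()
    print(f"{condition:>6}: homotopic r = {bundle['r']:+.3f}, "
          f"spectral peak at {peak:.3f} Hz, "
          f"max amplitude above 0.08 Hz = {above_band:.2e} %")

print("\nThe spectra live entirely below the 0.08 Hz low-pass cutoff; the")
print("interhemispheric correlation is the quantity the whole study tracks.")
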