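"""Preprocess one subject: band-pass + notch filter, EMD interference
removal, MVC normalization."""

import numpy as np

from tonus import FilterSpec, GeneratorConfig, ToneClass, preprocess_movement
from tonus.synth import generate_session

config = GeneratorConfig(seed=3, n_repetitions=5, mvc_duration=2.0)
session = generate_session("No01", ToneClass.NORMAL, config, np.random.default_rng(3))


def rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


raw = session.movement_emg
normalized, reference = preprocess_movement(
    raw, session.mvc, session.sampling_rate, FilterSpec()
)
print(f"raw biceps RMS        : {rms(raw[:, 0]):.4f} mV")
print(f"MVC reference (biceps): {reference.biceps:.4f} mV")
print(f"normalized biceps RMS : {rms(normalized[:, 0]):.4f}  (fraction of MVC)")
# After normalization amplitudes are unitless fractions of the subject's
# maximum voluntary contraction, so subjects with different electrode gains
# become comparable.
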