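"""Window a movement trial by elbow angle and extract the 11 descriptors."""

import numpy as np

from tonus import GeneratorConfig, RunConfig, ToneClass
from tonus.features import FEATURE_NAMES, build_feature_table
from tonus.pipeline import process_session
from tonus.synth import generate_session

config = GeneratorConfig(seed=5, n_repetitions=5, mvc_duration=2.0)
session = generate_session("Sp01", ToneClass.SPASTIC, config, np.random.default_rng(5))

windows, _ = process_session(session, RunConfig(generator=config))
print(f"{len(windows)} windows ({len(windows) // 2} repetitions x 2 muscles)")

table = build_feature_table(windows, session.sampling_rate)
print(f"feature table shape: {table.shape}  (11 biceps + 11 triceps + label)")
row = table.iloc[0]
for name in FEATURE_NAMES:
    print(f"  biceps_{name:<5} = {row[f'biceps_{name}']:.4f}")
# MAV/RMS measure amplitude (fractions of MVC), WL/SSC signal complexity,
# MNF/MDF the spectral centre of the 20-500 Hz band in Hz.
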