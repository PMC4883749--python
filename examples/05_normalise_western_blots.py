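"""The Western-blot normalisation pipeline on a miniature raw dataset.

Two conditions quantified on one blot with a calibrator sample: intensities
are corrected for loading (tubulin), calibrated across blots, averaged over
technical replicates within each biological replicate, and finally scaled
so that each molecule's largest mean is 1.  A third measurement with a weak
tubulin band (<20% of the blot maximum) is discarded by quality control.
"""

from pbnfit import RawBlotMeasurement, normalise_raw

raw = [
    # blot, condition, molecule, bio, tech, signal, tubulin, calibrator
    RawBlotMeasurement("b1", "untreated", "pERK", 1, 1, 8.0, 10.0),
    RawBlotMeasurement("b1", "untreated", "pERK", 1, 2, 8.4, 10.5),
    RawBlotMeasurement("b1", "untreated", "pERK", 2, 1, 7.6, 9.5),
    RawBlotMeasurement("b1", "treated", "pERK", 1, 1, 2.0, 10.0),
    RawBlotMeasurement("b1", "treated", "pERK", 2, 1, 2.4, 10.0),
    RawBlotMeasurement("b1", "treated", "pERK", 2, 2, 0.9, 1.5),   # fails QC
    RawBlotMeasurement("b1", "calibrator", "pERK", 0, 1, 4.0, 10.0,
                       is_calibrator=True),
]

dataset = normalise_raw(raw)
print(dataset.frame.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print()
print("'untreated' pERK is the per-molecule maximum, so its mean is 1.0;")
print("'treated' is expressed relative to it. The low-tubulin technical")
print("replicate was dropped before any ratio was formed, and the SD pools")
print("biological replicates after max-normalisation.")
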