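"""Published reference accuracies for slide-focus classification.

Per-focal-offset mean accuracies (percent) reported for the original
DeepFocus CNN and for the Lopez-style classical baseline on a scanned
six-slide test set.  These numbers serve as reference inputs for
aggregate bookkeeping (grand means, spreads, method differences); the
underlying slides are not distributable, so they cannot be recomputed
from pixels here.
"""

#: Mean accuracy (%) per focal offset (um), CNN.
CNN_ACCURACY_BY_OFFSET: dict[float, float] = {
    -2.5: 99.2,
    -2.0: 90.1,
    -1.5: 69.7,
    -0.5: 99.1,
    0.0: 96.9,
    0.5: 90.6,
    1.5: 93.2,
    2.0: 99.9,
    2.5: 100.0,
}

#: Mean accuracy (%) per focal offset (um), classical (Tenengrad + GLCM +
#: decision tree) baseline.
BASELINE_ACCURACY_BY_OFFSET: dict[float, float] = {
    -2.5: 78.5,
    -2.0: 56.8,
    -1.5: 35.9,
    -0.5: 78.1,
    0.0: 79.0,
    0.5: 78.9,
    1.5: 45.4,
    2.0: 74.6,
    2.5: 97.2,
}
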