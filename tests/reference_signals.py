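"""Published per-pair deviation (D) and ratio (R) tables for the two
six-class fixture periods, transcribed from the source publication's
signal table.  Rows are the source class i, columns the destination
class j, order FL, IFL, CL, O, CoL, W.  Used as regression references
for the expected-gain/-loss computation."""

import numpy as np

CLASSES = ["FL", "IFL", "CL", "O", "CoL", "W"]

D_GAIN = {
    "1992-2000": np.array([
        [0.00, -0.28, -0.13, -1.14, -0.09, 0.00],
        [1.72, 0.00, 0.11, -2.13, -0.10, 0.01],
        [-1.52, 0.40, 0.00, 3.38, -0.08, 0.00],
        [-0.15, -0.08, -0.02, 0.00, 0.28, 0.00],
        [-0.08, -0.01, 0.02, -0.09, 0.00, 0.00],
        [0.01, 0.00, 0.01, -0.02, 0.00, 0.00],
    ]),
    "2000-2013": np.array([
        [0.00, -0.12, -0.04, -2.10, -0.28, 0.02],
        [9.99, 0.00, 0.11, -3.07, 0.00, -0.01],
        [-7.03, 0.20, 0.00, 5.45, 0.06, -0.01],
        [-2.33, -0.06, -0.05, 0.00, 0.21, 0.00],
        [-0.59, -0.02, -0.01, -0.24, 0.00, 0.00],
        [-0.04, 0.01, 0.00, -0.03, -0.01, 0.00],
    ]),
}

D_LOSS = {
    "1992-2000": np.array([
        [0.00, 0.03, -0.03, -0.01, 0.01, 0.00],
        [1.99, 0.00, -1.47, -0.49, -0.04, -0.01],
        [-2.31, -2.47, 0.00, 4.94, -0.13, -0.04],
        [-0.07, -0.11, -0.11, 0.00, 0.29, 0.00],
        [-0.02, 0.00, -0.01, 0.02, 0.00, 0.00],
        [0.02, -0.01, -0.01, -0.01, 0.00, 0.00],
    ]),
    "2000-2013": np.array([
        [0.00, -0.07, -0.02, -0.10, 0.17, 0.03],
        [9.01, 0.00, -4.79, -3.85, -0.29, -0.06],
        [-4.61, -1.59, 0.00, 6.16, 0.14, -0.04],
        [-0.23, -0.07, -0.12, 0.00, 0.40, 0.00],
        [-0.01, 0.00, 0.00, -0.01, 0.00, 0.00],
        [0.02, 0.00, -0.01, -0.01, 0.00, 0.00],
    ]),
}

R_GAIN = {
    "1992-2000": np.array([
        [0.00, -0.82, -0.93, -1.00, -0.90, 0.00],
        [1.24, 0.00, 0.42, -1.00, -0.53, 0.00],
        [-0.87, 0.45, 0.00, 1.25, -0.33, 0.00],
        [-1.00, -1.00, -0.67, 0.00, 14.00, 0.00],
        [-1.00, -0.25, 2.00, -0.75, 0.00, 0.00],
        [0.50, 0.00, 0.00, -1.00, 0.00, 0.00],
    ]),
    "2000-2013": np.array([
        [0.00, -0.92, -0.24, -0.99, -0.58, 2.00],
        [1.29, 0.00, 0.44, -0.98, 0.00, -0.50],
        [-0.82, 0.91, 0.00, 1.56, 0.08, -0.50],
        [-1.00, -1.00, -0.71, 0.00, 0.95, 0.00],
        [-1.00, -1.00, -0.50, -1.00, 0.00, 0.00],
        [-0.50, 0.00, 0.00, -1.00, -1.00, 0.00],
    ]),
}

R_LOSS = {
    "1992-2000": np.array([
        [0.00, 1.00, -0.75, -1.00, 0.00, 0.00],
        [1.78, 0.00, -0.80, -0.98, -0.31, -0.50],
        [-0.91, -0.66, 0.00, 4.33, -0.45, -1.00],
        [-1.00, -1.00, -0.92, 0.00, 29.00, 0.00],
        [-1.00, 0.00, -0.25, 2.00, 0.00, 0.00],
        [2.00, -0.50, -0.50, -1.00, 0.00, 0.00],
    ]),
    "2000-2013": np.array([
        [0.00, -0.88, -0.13, -0.83, 5.67, 0.00],
        [1.04, 0.00, -0.93, -0.98, -0.29, -0.86],
        [-0.74, -0.79, 0.00, 2.21, 0.20, -0.80],
        [-1.00, -1.00, -0.86, 0.00, 13.33, 0.00],
        [-1.00, 0.00, 0.00, -1.00, 0.00, 0.00],
        [1.00, 0.00, 1.00, -1.00, 0.00, 0.00],
    ]),
}
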