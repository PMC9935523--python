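"""Frozen reference numbers used across the test suite.

PRINTED_RISK_TABLE holds the published average risk values per town,
receptor and metal (HQ_ing, HQ_derm, HI, CR; CR is None for Cu and Zn,
which carry no ingestion slope factor).  The printed values are
3-significant-figure roundings of the authors' unrounded town means, so
recomputation from the rounded means agrees within 1% relative.

IPIN_OF_MEANS holds the Integrated Nemerow Pollution Index evaluated at
each town's mean concentrations against the Mongolian permissible values
(3/100/100/300 mg/kg for Cd/Cu/Pb/Zn), computed by hand from the formula
IPI_N = sqrt((PI_avg^2 + PI_max^2)/2).
"""

PRINTED_RISK_TABLE = {
    ("Baganuur", "adult", "Cd"): (1.28e-3, 3.90e-4, 1.67e-3, 6.59e-6),
    ("Baganuur", "child", "Cd"): (1.05e-2, 1.68e-3, 1.21e-2, 1.35e-5),
    ("Nalaikh", "adult", "Cd"): (1.79e-3, 5.44e-4, 2.33e-3, 9.19e-6),
    ("Nalaikh", "child", "Cd"): (1.46e-2, 2.34e-3, 1.69e-2, 1.88e-5),
    ("Sharyn Gol", "adult", "Cd"): (2.15e-3, 6.55e-4, 2.81e-3, 1.11e-5),
    ("Sharyn Gol", "child", "Cd"): (1.76e-2, 2.82e-3, 2.04e-2, 2.26e-5),
    ("Baganuur", "adult", "Cu"): (5.03e-4, 5.11e-6, 5.09e-4, None),
    ("Baganuur", "child", "Cu"): (4.12e-3, 2.20e-5, 4.14e-3, None),
    ("Nalaikh", "adult", "Cu"): (5.09e-4, 5.16e-6, 5.14e-4, None),
    ("Nalaikh", "child", "Cu"): (4.16e-3, 2.22e-5, 4.18e-3, None),
    ("Sharyn Gol", "adult", "Cu"): (8.16e-4, 8.28e-6, 8.24e-4, None),
    ("Sharyn Gol", "child", "Cu"): (6.67e-3, 3.56e-5, 6.71e-3, None),
    ("Baganuur", "adult", "Pb"): (1.25e-2, 2.53e-4, 1.27e-2, 1.27e-7),
    ("Baganuur", "child", "Pb"): (1.02e-1, 1.09e-3, 1.03e-1, 2.60e-7),
    ("Nalaikh", "adult", "Pb"): (1.53e-2, 3.12e-4, 1.57e-2, 1.57e-7),
    ("Nalaikh", "child", "Pb"): (1.25e-1, 1.34e-3, 1.27e-1, 3.20e-7),
    ("Sharyn Gol", "adult", "Pb"): (2.91e-2, 5.91e-4, 2.97e-2, 2.97e-7),
    ("Sharyn Gol", "child", "Pb"): (2.38e-1, 2.54e-3, 2.40e-1, 6.07e-7),
    ("Baganuur", "adult", "Zn"): (2.54e-4, 3.87e-6, 2.58e-4, None),
    ("Baganuur", "child", "Zn"): (2.08e-3, 1.66e-5, 2.10e-3, None),
    ("Nalaikh", "adult", "Zn"): (3.62e-4, 5.52e-6, 3.68e-4, None),
    ("Nalaikh", "child", "Zn"): (2.96e-3, 2.37e-5, 2.99e-3, None),
    ("Sharyn Gol", "adult", "Zn"): (4.31e-4, 6.56e-6, 4.37e-4, None),
    ("Sharyn Gol", "child", "Zn"): (3.52e-3, 2.82e-5, 3.55e-3, None),
}

# hand evaluation of IPI_N from the town mean concentrations
IPIN_OF_MEANS = {
    "Baganuur": 0.2623,
    "Nalaikh": 0.3503,
    "Sharyn Gol": 0.5721,
}
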