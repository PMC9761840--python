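"""Packaged example dataset: acute pesticide toxicity to two African fish.

A published 96-h acute-toxicity study of four agrochemicals — the herbicide
atrazine, the fungicide mancozeb and the insecticides chlorpyrifos and
lambda-cyhalothrin — on fingerlings of the African catfish *Clarias
gariepinus* ("catfish") and the Nile tilapia *Oreochromis niloticus*
("tilapia"), together with bioassays of their binary and quaternary
equitoxic mixtures. Ten fish per aquarium in duplicate (20 per
concentration group), hourly mortality counts, 96-h study window.

Contents
--------
* ``LC50_96H`` — single-pesticide 96-h LC50s (mg/L).
* ``SINGLE_LT50_POINTS`` — per-concentration median lethal times (h) of the
  single pesticides; refitting these with :func:`~lethaltime.regression.fit_loglog`
  reproduces ``REGRESSION`` to 3 decimals.
* ``REGRESSION`` — the published log-log coefficients ln(LT50) = a + b*ln(C).
* ``MIXTURE_RATIOS`` — equitoxic mixing-ratio weights per species; the
  quaternary ratios are the single-pesticide LC50s themselves (the worked
  mixture tables use these, not the rounded recipe ratio printed alongside
  the stock solutions).
* ``PUBLISHED_MIX_LT50`` — the published mixture LT50 cells, with an
  ``include`` flag marking the internally consistent cells (those that the
  published report itself computed from its own coefficients without
  transcription slips; the catfish atrazine-mancozeb block, whose published
  values swapped the two components' coefficient sets, is excluded).
* ``PUBLISHED_MORTALITY`` — predicted-mortality integer cells for the
  atrazine-chlorpyrifos mixtures (per cent at 24/48/72/96 h).
* ``COMPONENT_LCX`` — single-pesticide lethal concentrations at the
  5/15/35/60/90% effect levels (mg/L), as tabulated.
* ``CA_TRANSPOSED`` — mixtures whose published proportion columns are
  paired with the components in transposed order.
* ``OBSERVED_MORTALITY`` — observed mixture-bioassay mortality
  (per cent of 20 fish at 24/48/72/96 h) where the published table is
  unambiguous.
* ``PREDICTED_VS_OBSERVED`` — observed and model-predicted mixture 96-h
  LC50s with the published model-deviation ratios.

All concentrations mg/L (lambda-cyhalothrin entries already converted from
ug/L), all times hours.
"""

from __future__ import annotations

from .bioassay import LtcRegression, MixtureSpec, make_mixture

CATFISH = "catfish"
TILAPIA = "tilapia"
SPECIES = (CATFISH, TILAPIA)

ATRAZINE = "atrazine"
MANCOZEB = "mancozeb"
CHLORPYRIFOS = "chlorpyrifos"
LAMBDA = "lambda-cyhalothrin"
PESTICIDES = (ATRAZINE, MANCOZEB, CHLORPYRIFOS, LAMBDA)

# single-pesticide 96-h LC50, mg/L
LC50_96H = {
    (CATFISH, ATRAZINE): 17.463,
    (CATFISH, CHLORPYRIFOS): 0.515,
    (CATFISH, MANCOZEB): 24.383,
    (CATFISH, LAMBDA): 0.000434,
    (TILAPIA, ATRAZINE): 10.926,
    (TILAPIA, CHLORPYRIFOS): 0.111,
    (TILAPIA, MANCOZEB): 3.028,
    (TILAPIA, LAMBDA): 0.008412,
}

# (concentration mg/L, LT50 h) pairs of the single-pesticide bioassays;
# LT50s beyond 96 h are probit extrapolations and belong in the fit.
SINGLE_LT50_POINTS = {
    (CATFISH, ATRAZINE): [
        (13.0, 148.8), (16.0, 149.7), (19.0, 103.85), (21.0, 53.55), (24.0, 16.79),
    ],
    (CATFISH, CHLORPYRIFOS): [
        (0.25, 538.44), (0.40, 209.83), (0.55, 49.59), (0.70, 29.85), (1.00, 8.28),
    ],
    (CATFISH, MANCOZEB): [
        (8.0, 1115.47), (20.0, 226.26), (32.0, 80.56), (38.0, 39.66), (42.0, 13.01),
    ],
    (CATFISH, LAMBDA): [
        (0.00025, 214.82), (0.00038, 103.90), (0.00050, 37.17),
        (0.00063, 10.40), (0.00075, 3.24),
    ],
    (TILAPIA, ATRAZINE): [
        (6.0, 253.92), (9.0, 156.13), (14.0, 58.11), (21.0, 27.49),
    ],
    (TILAPIA, CHLORPYRIFOS): [
        (0.08, 646.81), (0.10, 245.68), (0.13, 22.02), (0.17, 10.19),
    ],
    (TILAPIA, MANCOZEB): [
        (1.4, 2769.46), (2.2, 500.02), (3.2, 58.07), (4.8, 13.56),
    ],
    (TILAPIA, LAMBDA): [
        (0.0025, 317.13), (0.0050, 221.85), (0.0075, 110.75),
        (0.0100, 42.61), (0.0125, 28.52), (0.0150, 15.20),
    ],
}

# published log-log coefficients ln(LT50) = a + b*ln(C)
REGRESSION = {
    (CATFISH, ATRAZINE): LtcRegression(14.033, -3.358, 0.758, 5, (13.0, 24.0)),
    (CATFISH, CHLORPYRIFOS): LtcRegression(2.211, -3.069, 0.984, 5, (0.25, 1.0)),
    (CATFISH, MANCOZEB): LtcRegression(12.244, -2.397, 0.892, 5, (8.0, 42.0)),
    (CATFISH, LAMBDA): LtcRegression(-25.581, -3.784, 0.915, 5, (0.00025, 0.00075)),
    (TILAPIA, ATRAZINE): LtcRegression(8.906, -1.826, 0.982, 4, (6.0, 21.0)),
    (TILAPIA, CHLORPYRIFOS): LtcRegression(-8.373, -5.889, 0.939, 4, (0.08, 0.17)),
    (TILAPIA, MANCOZEB): LtcRegression(9.482, -4.439, 0.988, 4, (1.4, 4.8)),
    (TILAPIA, LAMBDA): LtcRegression(-4.161, -1.725, 0.884, 6, (0.0025, 0.0150)),
}

AM = "atrazine-mancozeb"
AC = "atrazine-chlorpyrifos"
AL = "atrazine-lambda-cyhalothrin"
MC = "mancozeb-chlorpyrifos"
ML = "mancozeb-lambda-cyhalothrin"
LC = "lambda-cyhalothrin-chlorpyrifos"
QUAT = "quaternary"
MIXTURES = (AM, AC, AL, MC, ML, LC, QUAT)

# equitoxic mixing-ratio weights (mg/L scale; quaternary = the LC50s)
MIXTURE_RATIOS = {
    (CATFISH, AM): [(ATRAZINE, 1.0), (MANCOZEB, 1.39)],
    (CATFISH, AC): [(ATRAZINE, 33.95), (CHLORPYRIFOS, 1.0)],
    (CATFISH, AL): [(ATRAZINE, 40.28), (LAMBDA, 0.001)],
    (CATFISH, MC): [(MANCOZEB, 47.35), (CHLORPYRIFOS, 1.0)],
    (CATFISH, ML): [(MANCOZEB, 56.18), (LAMBDA, 0.001)],
    (CATFISH, LC): [(LAMBDA, 0.001), (CHLORPYRIFOS, 1.18)],
    (CATFISH, QUAT): [
        (ATRAZINE, 17.463), (MANCOZEB, 24.383),
        (CHLORPYRIFOS, 0.515), (LAMBDA, 0.000434),
    ],
    (TILAPIA, AM): [(ATRAZINE, 3.61), (MANCOZEB, 1.0)],
    (TILAPIA, AC): [(ATRAZINE, 98.47), (CHLORPYRIFOS, 1.0)],
    (TILAPIA, AL): [(ATRAZINE, 12.99), (LAMBDA, 0.01)],
    (TILAPIA, MC): [(MANCOZEB, 27.3), (CHLORPYRIFOS, 1.0)],
    (TILAPIA, ML): [(MANCOZEB, 3.60), (LAMBDA, 0.01)],
    (TILAPIA, LC): [(LAMBDA, 1.0), (CHLORPYRIFOS, 13.21)],
    (TILAPIA, QUAT): [
        (ATRAZINE, 10.926), (MANCOZEB, 3.028),
        (CHLORPYRIFOS, 0.111), (LAMBDA, 0.008412),
    ],
}


def mixture_spec(species: str, mixture: str) -> MixtureSpec:
    """The packaged :class:`MixtureSpec` for one species/mixture."""
    return make_mixture(mixture, MIXTURE_RATIOS[(species, mixture)], species=species)


def regression_coeffs(species: str) -> dict[str, LtcRegression]:
    """Component name -> published log-log coefficients for one species."""
    return {p: REGRESSION[(species, p)] for p in PESTICIDES}


# published mixture LT50 cells: (total mg/L, LT50_mix h, internally consistent)
PUBLISHED_MIX_LT50 = {
    (CATFISH, AM): [
        # published block computed with the two components' coefficient sets
        # swapped (and the first row proportion-normalised); never reproducible
        # from the coefficients as declared.
        (5.0, 34869.6, False), (10.0, 425.35, False), (15.0, 79.42, False),
        (20.0, 23.85, False), (25.0, 9.37, False),
    ],
    (CATFISH, AC): [
        (4.0, 3181.6, True), (8.0, 156.62, True), (12.0, 26.88, True),
        (16.0, 7.70, True), (20.0, 2.92, True),
    ],
    (CATFISH, AL): [
        (3.5, 5289.83, True), (7.5, 190.97, True), (11.5, 29.65, True),
        (15.5, 8.07, True), (19.5, 2.97, True),
    ],
    (CATFISH, MC): [
        # the published 1.5-10.5 cells disagree with their own printed
        # row inputs (Ca/LTa etc.) by 0.5-2%
        (1.5, 55090.41, False), (4.5, 1319.15, False), (7.5, 232.63, False),
        (10.5, 74.18, True), (15.5, 19.76, True),
    ],
    (CATFISH, ML): [
        (4.0, 1872.10, True), (8.0, 177.72, True), (12.0, 144.83, False),
        (16.0, 16.87, True), (20.0, 7.91, True),
    ],
    (CATFISH, LC): [
        (0.05, 1800890.66, True), (0.25, 2579.26, True), (0.45, 235.93, True),
        (0.65, 52.84, True), (0.85, 17.74, True),
    ],
    (CATFISH, QUAT): [
        (8.0, 985.14, True), (12.0, 231.97, True), (16.0, 81.94, True),
        (20.0, 36.20, True), (24.0, 18.44, True),
    ],
    (TILAPIA, AM): [
        (1.5, 4676.83, True), (5.0, 153.00, True), (8.5, 32.39, True),
        (12.0, 11.11, True), (15.5, 4.70, True),
    ],
    (TILAPIA, AC): [
        (3.0, 340.30, True), (5.0, 80.31, True), (7.0, 31.00, True),
        (9.0, 15.19, True), (11.0, 8.57, True),
    ],
    (TILAPIA, AL): [
        # published block computed with an atrazine intercept of ~8.805
        # rather than the declared 8.906 (a uniform +10.5% offset)
        (2.5, 501.43, False), (5.0, 70.72, False), (7.5, 22.49, False),
        (10.0, 9.97, False), (12.5, 5.31, False),
    ],
    (TILAPIA, MC): [
        # all but the 3.0 cell disagree with their own printed row inputs
        (1.5, 1696.58, False), (2.25, 186.99, False), (3.0, 39.11, True),
        (3.75, 11.62, False), (4.5, 4.31, False),
    ],
    (TILAPIA, ML): [
        (1.3, 3059.71, True), (2.1, 232.65, True), (2.9, 40.49, True),
        (3.7, 10.79, True), (4.5, 3.72, True),
    ],
    (TILAPIA, LC): [
        (0.12, 751.57, True), (0.15, 172.88, True), (0.18, 50.46, True),
        (0.21, 17.63, True), (0.24, 7.06, True),
    ],
    (TILAPIA, QUAT): [
        (3.0, 672.17, True), (5.5, 119.02, True), (8.0, 39.76, True),
        (10.5, 17.36, True), (13.0, 8.73, True),
    ],
}

# published predicted-mortality integers (percent at 24/48/72/96 h)
PUBLISHED_MORTALITY = {
    (CATFISH, AC): {
        4.0: (1, 1, 2, 3), 8.0: (13, 23, 31, 38), 12.0: (47, 64, 73, 78),
        16.0: (76, 86, 90, 93), 20.0: (89, 94, 96, 97),
    },
    (TILAPIA, AC): {
        3.0: (7, 12, 17, 22), 5.0: (23, 37, 47, 54), 7.0: (44, 61, 70, 76),
        9.0: (61, 76, 83, 86), 11.0: (74, 85, 89, 92),
    },
}

EFFECT_LEVELS = (0.05, 0.15, 0.35, 0.60, 0.90)

# single-pesticide LCx (mg/L) at the 5/15/35/60/90% effect levels
COMPONENT_LCX = {
    (CATFISH, ATRAZINE): (7.025, 10.894, 15.033, 19.094, 25.631),
    (CATFISH, MANCOZEB): (5.363, 12.398, 19.928, 27.313, 39.203),
    (CATFISH, CHLORPYRIFOS): (0.125, 0.270, 0.424, 0.575, 0.819),
    (CATFISH, LAMBDA): (0.000186, 0.000278, 0.000376, 0.000473, 0.000628),
    (TILAPIA, ATRAZINE): (3.95, 5.76, 8.61, 12.78, 24.13),
    (TILAPIA, MANCOZEB): (1.87, 2.23, 2.70, 3.26, 4.42),
    (TILAPIA, CHLORPYRIFOS): (0.08, 0.09, 0.10, 0.12, 0.15),
    (TILAPIA, LAMBDA): (0.003, 0.004, 0.007, 0.010, 0.020),
}

# mixtures whose published CA-table proportion columns pair the components
# in transposed order relative to the declared recipe
CA_TRANSPOSED = {(CATFISH, AM)}

# published CA-table mixture LCx cells (mg/L) for the two reference mixtures
PUBLISHED_CA_LCX = {
    (CATFISH, AM): (6.22, 11.48, 16.76, 21.84, 29.97),
    (TILAPIA, AM): (3.18, 4.29, 5.84, 7.83, 12.26),
}

# observed mixture-bioassay mortality, percent of 20 fish at 24/48/72/96 h;
# only the unambiguously tabulated blocks are carried
OBSERVED_MORTALITY = {
    (CATFISH, AM): [
        (4.61, (10, 15, 30, 35)), (9.22, (10, 45, 65, 65)),
        (13.83, (15, 55, 70, 70)), (18.44, (45, 85, 90, 100)),
        (23.05, (70, 95, 100, 100)),
    ],
    (CATFISH, AC): [
        (1.99, (20, 25, 30, 65)), (3.98, (60, 60, 65, 95)),
        (5.97, (65, 80, 95, 100)), (7.96, (90, 95, 100, 100)),
        (9.95, (100, 100, 100, 100)),
    ],
    (CATFISH, AL): [
        (7.6, (5, 10, 25, 45)), (10.4, (10, 20, 45, 55)),
        (13.0, (30, 35, 55, 60)), (15.6, (40, 45, 60, 75)),
        (18.2, (45, 55, 70, 80)), (20.8, (85, 95, 100, 100)),
    ],
    (CATFISH, ML): [
        (4.33, (10, 20, 25, 25)), (5.05, (25, 25, 35, 40)),
        (5.78, (35, 35, 45, 55)), (6.5, (40, 40, 55, 60)),
        (7.22, (55, 55, 65, 75)),
    ],
    (CATFISH, LC): [
        (0.11, (10, 15, 20, 25)), (0.14, (25, 25, 35, 35)),
        (0.18, (45, 55, 55, 60)), (0.21, (60, 65, 75, 80)),
        (0.25, (80, 85, 100, 100)),
    ],
    (TILAPIA, AM): [
        (9.56, (0, 5, 5, 10)), (10.76, (15, 35, 35, 45)),
        (11.95, (35, 50, 65, 70)), (13.15, (45, 65, 75, 85)),
        (14.34, (75, 90, 100, 100)),
    ],
    (TILAPIA, AC): [
        (6.99, (0, 5, 5, 10)), (8.39, (10, 15, 20, 25)),
        (9.79, (35, 40, 55, 65)), (11.18, (45, 55, 65, 80)),
        (12.58, (55, 70, 85, 95)),
    ],
    (TILAPIA, AL): [
        (16.12, (0, 0, 5, 10)), (22.57, (5, 5, 10, 25)),
        (29.02, (10, 20, 35, 45)), (35.47, (25, 30, 45, 65)),
        (41.91, (55, 75, 85, 100)),
    ],
    (TILAPIA, MC): [
        (3.87, (0, 5, 10, 10)), (4.84, (10, 15, 20, 35)),
        (5.81, (30, 35, 45, 55)), (6.78, (55, 60, 65, 80)),
        (7.74, (95, 100, 100, 100)),
    ],
    (TILAPIA, ML): [
        (4.5, (5, 10, 10, 10)), (6.74, (20, 25, 35, 40)),
        (8.99, (35, 45, 55, 60)), (11.24, (55, 70, 75, 80)),
        (13.49, (80, 95, 100, 100)),
    ],
    (TILAPIA, LC): [
        (0.19, (10, 20, 25, 25)), (0.29, (40, 40, 55, 55)),
        (0.38, (60, 65, 70, 75)), (0.48, (80, 80, 85, 85)),
        (0.57, (100, 100, 100, 100)),
    ],
    (TILAPIA, QUAT): [
        (1.95, (5, 5, 10, 10)), (3.91, (25, 30, 35, 35)),
        (5.86, (40, 45, 55, 60)), (7.81, (70, 75, 75, 80)),
        (11.72, (100, 100, 100, 100)),
    ],
}

# observed and model-predicted mixture 96-h LC50 (mg/L) with the published
# model-deviation ratios: {..: (observed, hm, ca, mdr_hm, mdr_ca)}
PREDICTED_VS_OBSERVED = {
    (CATFISH, AM): (11.1, 14.3, 18.5, 1.28, 1.67),
    (CATFISH, AC): (9.2, 8.5, 8.3, 0.92, 0.90),
    (CATFISH, AL): (22.1, 8.7, 8.3, 0.39, 0.38),
    (CATFISH, MC): (5.3, 9.7, 11.3, 1.83, 2.13),
    (CATFISH, ML): (7.5, 9.5, 11.3, 1.27, 1.51),
    (CATFISH, LC): (0.27, 0.55, 0.24, 2.04, 0.89),
    (CATFISH, QUAT): (4.6, 14.9, 9.8, 3.24, 2.13),
    (TILAPIA, AM): (6.7, 5.9, 6.9, 0.88, 1.03),
    (TILAPIA, AC): (2.6, 4.8, 5.6, 1.85, 2.15),
    (TILAPIA, AL): (9.3, 4.51, 5.3, 0.49, 0.57),
    (TILAPIA, MC): (1.2, 2.5, 1.487, 2.08, 1.24),
    (TILAPIA, ML): (5.7, 2.4, 1.6, 0.42, 0.28),
    (TILAPIA, LC): (0.15, 0.16, 0.06, 1.07, 0.40),
    (TILAPIA, QUAT): (1.09, 6.0, 3.4, 5.50, 3.12),
}


def mixture_totals(species: str, mixture: str) -> list[float]:
    """The total-concentration grid used for one species/mixture."""
    return [row[0] for row in PUBLISHED_MIX_LT50[(species, mixture)]]
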