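"""Published hit tables of the 386-clone gene-trap ESC radiation screen.

The original screen's raw well data were released only as supplementary
spreadsheets, but its hit tables — per-gene ΔV / Z / p for the viability
assay and log₁₀ β-gal ratio / Z / p for the expression assay, at the
0 → 0.5 Gy and 0 → 4 Gy dose contrasts — are printed in full.  They are
reproduced here as machine-readable constants for two purposes:

* internal-consistency validation: the printed Z ↔ statistic pairs pin
  down the null parameters (μ, σ) actually used per dose contrast, which
  :func:`implied_null_parameters` recovers by least squares, and the
  printed p-values must equal ``two_tailed_p(Z)`` to print precision;
* calibrating the synthetic-screen generator's null widths to the study.

ΔV values are stored as fractions (the source prints percentages).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# (gene, dose_gy, delta_v fraction, z, printed p) — viability hits, p < 0.01
VIABILITY_HITS = (
    # decreased viability, 0 -> 0.5 Gy
    ("Prdx3",   0.5, -0.3089, -4.41953, 9.89e-06),
    ("Bcap31",  0.5, -0.3051, -4.36329, 1.28e-05),
    ("Bach1",   0.5, -0.2249, -3.15661, 1.596e-03),
    ("Nrf1",    0.5, -0.2237, -3.13909, 1.695e-03),
    ("Vamp12",  0.5, -0.2207, -3.09443, 1.972e-03),
    # increased viability, 0 -> 0.5 Gy
    ("Mcm2",    0.5,  0.2578,  4.100149, 4.13e-05),
    ("Cradd",   0.5,  0.2446,  3.901591, 9.56e-05),
    ("Rbbp5",   0.5,  0.2274,  3.643607, 2.69e-04),
    ("Lims1",   0.5,  0.2258,  3.619399, 2.95e-04),
    ("Ctnna1",  0.5,  0.1996,  3.224992, 1.26e-03),
    ("Arl6ip5", 0.5,  0.1987,  3.212631, 1.315e-03),
    ("Dpagt1",  0.5,  0.1955,  3.164071, 1.556e-03),
    ("Rfx2",    0.5,  0.1928,  3.123158, 1.789e-03),
    ("Thrap3",  0.5,  0.1898,  3.078622, 2.08e-03),
    ("Casc3",   0.5,  0.1837,  2.98651,  2.822e-03),
    ("Ttl",     0.5,  0.1836,  2.985033, 2.835e-03),
    ("Nrip1",   0.5,  0.1772,  2.88807,  3.876e-03),
    ("Mll3",    0.5,  0.1769,  2.883578, 3.932e-03),
    ("Psmb10",  0.5,  0.1618,  2.65656,  7.894e-03),
    ("Topors",  0.5,  0.1587,  2.611167, 9.023e-03),
    ("Exo1",    0.5,  0.1568,  2.581592, 9.835e-03),
    # increased viability, 0 -> 4 Gy
    ("Cdc25c",  4.0,  0.3977,  5.313806, 1.07e-07),
    ("Rab8a",   4.0,  0.3636,  4.887382, 1.02e-06),
    ("Bclaf1",  4.0,  0.2979,  4.065455, 4.79e-05),
    ("Bcl7a",   4.0,  0.2351,  3.280737, 1.035e-03),
    ("Kif22",   4.0,  0.1935,  2.760707, 5.768e-03),
    ("Cux1",    4.0,  0.1916,  2.736151, 6.216e-03),
    ("Scpep1",  4.0,  0.1791,  2.58025,  9.873e-03),
)

# (gene, dose_gy, log10 beta-gal ratio, z, printed p; p=0.0 means underflow
# of the source's rendering, not a true zero) — expression hits, p < 0.01
EXPRESSION_HITS = (
    # decreased expression, 0 -> 0.5 Gy
    ("Brcc3",   0.5, -1.77153, -12.4129, 0.0),
    ("Grb7",    0.5, -0.62621, -4.24135, 2.22e-05),
    ("Nap1l4",  0.5, -0.51406, -3.44121, 5.79e-04),
    ("Cep68",   0.5, -0.51189, -3.42576, 6.13e-04),
    ("Anapc7",  0.5, -0.50525, -3.37836, 7.29e-04),
    ("Rfx2",    0.5, -0.45217, -2.99962, 2.703e-03),
    ("Rhbdd3",  0.5, -0.40548, -2.66652, 7.664e-03),
    # decreased expression, 0 -> 4 Gy
    ("Brcc3",   4.0, -1.85002, -9.34039, 0.0),
    ("Ing4",    4.0, -0.92325, -4.48835, 7.18e-06),
    ("Epc1",    4.0, -0.89975, -4.36531, 1.27e-05),
    ("Mtap4",   4.0, -0.89935, -4.3632,  1.28e-05),
    ("Atp2b1",  4.0, -0.63371, -2.97248, 2.954e-03),
    ("Adnp2",   4.0, -0.60024, -2.79726, 5.154e-03),
    ("Diablo",  4.0, -0.59001, -2.74367, 6.076e-03),
    # increased expression, 0 -> 4 Gy
    ("Serinc3", 4.0,  1.180251, 6.524403, 6.83e-11),
    ("Pex14",   4.0,  0.739167, 4.21514,  2.5e-05),
    ("Dstn",    4.0,  0.468382, 2.797459, 5.151e-03),
    # increased expression, 0 -> 0.5 Gy
    ("Dstn",    0.5,  0.441173, 3.374142, 7.4e-04),
    ("Pex14",   0.5,  0.383902, 2.965529, 3.022e-03),
    ("Ptbp2",   0.5,  0.368237, 2.853763, 4.32e-03),
    ("Prdx3",   0.5,  0.357476, 2.776985, 5.487e-03),
    ("Ccnb1",   0.5,  0.351157, 2.731898, 6.297e-03),
    ("Tnfaip8", 0.5,  0.345919, 2.69453,  7.049e-03),
)

#: number of genes assayed in the screen; the enrichment background size
BACKGROUND_SIZE = 386


def viability_hit_table() -> pd.DataFrame:
    """Printed viability hits as a frame (delta_v as a fraction)."""
    return pd.DataFrame(
        VIABILITY_HITS, columns=["gene_symbol", "dose_gy", "delta_v", "z", "p_printed"]
    )


def expression_hit_table() -> pd.DataFrame:
    """Printed expression hits as a frame (log10_ratio in log₁₀ units)."""
    return pd.DataFrame(
        EXPRESSION_HITS,
        columns=["gene_symbol", "dose_gy", "log10_ratio", "z", "p_printed"],
    )


def implied_null_parameters(
    statistic: np.ndarray, z: np.ndarray
) -> tuple[float, float, np.ndarray]:
    """Back-derive the null (μ, σ) from printed (statistic, Z) pairs.

    Since Z = (x − μ)/σ is affine in x, ordinary least squares of Z on x
    recovers σ = 1/slope and μ = −intercept·σ; residuals measure how
    consistently the published rows share one null (they are limited only
    by the rounding of the printed statistic).

    Returns ``(mu, sigma, residuals)``.
    """
    statistic = np.asarray(statistic, dtype=float)
    z = np.asarray(z, dtype=float)
    if statistic.size < 2:
        raise ValueError("need at least two (statistic, Z) pairs")
    slope, intercept = np.polyfit(statistic, z, 1)
    sigma = 1.0 / slope
    mu = -intercept * sigma
    residuals = z - (statistic - mu) / sigma
    return float(mu), float(sigma), residuals
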