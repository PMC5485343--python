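"""Independent oracles the tests compare the package against.

These deliberately share no code with the package: the ANOVA oracle builds
explicit dummy design matrices and computes sums of squares as differences of
least-squares residuals between nested models; the cap-area oracle integrates
the surface element numerically.
"""

import numpy as np
from scipy.integrate import quad


def anova_projection_oracle(table, dv="area_mm2", subject="animal_id", within="timepoint_h", between="arm"):
    """Split-plot sums of squares via nested-model least-squares projections."""
    df = table.sort_values([between, subject, within]).reset_index(drop=True)
    y = df[dv].to_numpy(dtype=float)

    def dummies(col):
        levels = sorted(df[col].unique())
        return np.column_stack([(df[col] == lv).to_numpy(float) for lv in levels])

    G = dummies(between)
    U = dummies(subject)
    T = dummies(within)
    # cell (group x time) dummies
    cells = df[between].astype(str) + "|" + df[within].astype(str)
    C = np.column_stack([(cells == lv).to_numpy(float) for lv in sorted(cells.unique())])
    ones = np.ones((len(y), 1))

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        return float(resid @ resid)

    rss_1 = rss(ones)
    rss_g = rss(np.hstack([ones, G]))
    rss_gu = rss(np.hstack([ones, G, U]))
    rss_gut = rss(np.hstack([ones, G, U, T]))
    rss_full = rss(np.hstack([ones, G, U, T, C]))
    return {
        "treatment": rss_1 - rss_g,
        "subjects": rss_g - rss_gu,
        "time": rss_gu - rss_gut,
        "time:treatment": rss_gut - rss_full,
        "residual": rss_full,
        "total": rss_1,
    }


def cap_area_quadrature(R, r):
    """Spherical-cap area by numerical integration of the surface element.

    A = integral over the disc of dA / cos(tilt) = 2 pi int_0^r rho / sqrt(1 - rho^2/R^2) drho.
    """
    val, _ = quad(lambda rho: 2 * np.pi * rho / np.sqrt(1 - (rho / R) ** 2), 0.0, r)
    return val


def pearson_formula(x, y):
    """Sample correlation straight from the covariance formula."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc)))
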