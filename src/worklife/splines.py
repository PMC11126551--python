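"""Restricted (natural) cubic spline basis for the age effect.

The basis is the truncated-power parameterization of a natural cubic
spline: cubic between the boundary knots and constrained to be linear
beyond them.  With K knots the basis has K-1 columns: the identity
(linear) column plus K-2 restricted cubic terms.  The nonlinear columns
are normalized by the squared knot range so that their scale is
comparable to the linear column.
"""

from __future__ import annotations

import numpy as np

from .errors import ConfigurationError

#: Conventional quantile placements for K knots over the observed ages.
KNOT_QUANTILES: dict[int, tuple[float, ...]] = {
    3: (0.10, 0.50, 0.90),
    4: (0.05, 0.35, 0.65, 0.95),
    5: (0.05, 0.275, 0.50, 0.725, 0.95),
    6: (0.05, 0.23, 0.41, 0.59, 0.77, 0.95),
    7: (0.025, 0.1833, 0.3417, 0.50, 0.6583, 0.8167, 0.975),
}


def validate_knots(knots) -> np.ndarray:
    t = np.asarray(knots, dtype=float)
    if t.ndim != 1 or t.size < 3:
        raise ConfigurationError("age spline requires at least 3 knots")
    if np.any(np.diff(t) <= 0):
        raise ConfigurationError(f"knots must be strictly increasing, got {t.tolist()}")
    return t


def rcs_basis(x, knots) -> np.ndarray:
    """Evaluate the restricted cubic spline basis.

    Parameters
    ----------
    x : array-like of shape (n,)
        Ages (years) at which to evaluate the basis.
    knots : array-like of shape (K,), K >= 3
        Strictly increasing knot locations (years).

    Returns
    -------
    ndarray of shape (n, K-1)
        Column 0 is ``x`` itself; columns 1..K-2 are the restricted cubic
        terms, identically zero at and below the first knot and linear in
        ``x`` beyond the last knot.
    """
    t = validate_knots(knots)
    x = np.asarray(x, dtype=float)
    scale = (t[-1] - t[0]) ** 2
    denom = t[-1] - t[-2]

    def pos_cube(u):
        return np.maximum(u, 0.0) ** 3

    cols = [x]
    for j in range(len(t) - 2):
        term = (
            pos_cube(x - t[j])
            - pos_cube(x - t[-2]) * (t[-1] - t[j]) / denom
            + pos_cube(x - t[-1]) * (t[-2] - t[j]) / denom
        )
        cols.append(term / scale)
    return np.column_stack(cols)


def default_knots(ages, n_knots: int) -> np.ndarray:
    """Place ``n_knots`` knots at conventional quantiles of observed ages."""
    if n_knots not in KNOT_QUANTILES:
        raise ConfigurationError(
            f"n_knots must be one of {sorted(KNOT_QUANTILES)}, got {n_knots}"
        )
    ages = np.asarray(ages, dtype=float)
    q = np.quantile(ages, KNOT_QUANTILES[n_knots])
    if np.any(np.diff(q) <= 0):
        raise ConfigurationError(
            "observed ages too concentrated to place distinct spline knots; "
            "supply explicit age_knots"
        )
    return q
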