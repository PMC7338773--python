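"""First-order normalized Legendre polynomial basis on [-1, 1].

The reaction-norm trajectory is modelled with Legendre polynomials of
order 1, in the *normalized* (orthonormal) form used throughout livestock
random-regression models:

.. math::

    \\phi_0(x) = \\sqrt{1/2}, \\qquad \\phi_1(x) = \\sqrt{3/2}\\, x

so that :math:`\\int_{-1}^{1} \\phi_i(x)\\phi_j(x)\\,dx = \\delta_{ij}`.
The normalized form (not the raw ``(1, x)`` pair) is what reproduces the
published across-environment genetic correlations, and it is used
consistently for the fixed regression, the random genetic regression and
all derived quantities.
"""

from __future__ import annotations

import numpy as np

PHI0 = np.sqrt(0.5)
_PHI1_SCALE = np.sqrt(1.5)


def legendre_basis(x):
    """Evaluate the normalized order-1 Legendre basis at ``x``.

    Parameters
    ----------
    x : float or array_like
        Standardized environmental covariate value(s) in ``[-1, 1]``.

    Returns
    -------
    (phi0, phi1)
        ``phi0`` is the constant :math:`\\sqrt{1/2}` (broadcast to the shape
        of ``x``), ``phi1`` is :math:`\\sqrt{3/2}\\,x`.

    Raises
    ------
    ValueError
        If any ``|x| > 1`` (beyond a tiny numerical slack).
    """
    x = np.asarray(x, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-9):
        bad = np.asarray(x)[np.abs(x) > 1.0 + 1e-9]
        raise ValueError(f"covariate outside [-1, 1]: {bad[:5]}")
    phi0 = np.full_like(x, PHI0)
    phi1 = _PHI1_SCALE * x
    if phi0.ndim == 0:
        return float(phi0), float(phi1)
    return phi0, phi1


def phi_matrix(grid) -> np.ndarray:
    """Basis matrix ``Phi`` with one row ``(phi0(x), phi1(x))`` per grid point."""
    phi0, phi1 = legendre_basis(np.atleast_1d(np.asarray(grid, dtype=float)))
    return np.column_stack([phi0, phi1])
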