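"""Small shared helpers (seed handling, design-matrix checks)."""

from __future__ import annotations

import numpy as np

from .errors import EstimationError

MAX_SEED = 2**31


def as_rng(seed) -> np.random.Generator:
    """Normalize ``seed`` (int, SeedSequence, Generator or None) to a Generator."""
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def child_seeds(seed, n: int) -> list[int]:
    """Derive ``n`` independent integer sub-seeds (< 2**31) from a master seed.

    Uses numpy's counter-based SeedSequence spawning so the derived streams
    are statistically independent and the mapping is reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0]) % MAX_SEED for child in ss.spawn(n)]


def tagged_seed(*parts: int) -> int:
    """Deterministic integer seed derived from a tuple of integer tags."""
    ss = np.random.SeedSequence([int(p) for p in parts])
    return int(ss.generate_state(1)[0]) % MAX_SEED


def check_full_rank(X: np.ndarray, names: list[str]) -> None:
    """Raise :class:`EstimationError` naming (near-)collinear columns of ``X``."""
    if X.shape[0] < X.shape[1]:
        raise EstimationError(
            f"design has more columns ({X.shape[1]}) than rows ({X.shape[0]})"
        )
    # QR with column pivoting localizes the dependent columns.
    import scipy.linalg

    _, R, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = max(X.shape) * np.finfo(float).eps * (diag.max() if diag.size else 0.0)
    bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
    if bad:
        raise EstimationError("design matrix is rank deficient; collinear columns: "
                              + ", ".join(sorted(bad)))
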