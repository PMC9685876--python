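"""Internal helpers: seeded random substreams, residualization, BH q-values."""

from __future__ import annotations

import zlib

import numpy as np
from statsmodels.stats.multitest import multipletests

__all__ = ["rng_stream", "residualize", "bh_qvalues"]


def rng_stream(seed: int, *labels: object) -> np.random.Generator:
    """A named random substream derived from one root seed.

    Every source of randomness in the package draws from a stream obtained
    here, so regenerating one artifact (e.g. the contact matrix) never
    perturbs another (e.g. the genotypes). Labels are hashed with CRC32 into
    the SeedSequence spawn key, which keeps streams statistically independent
    while staying reproducible across platforms.
    """
    key = tuple(zlib.crc32(str(label).encode("utf-8")) for label in labels)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


def residualize(values: np.ndarray, covariates: np.ndarray | None) -> np.ndarray:
    """Project out covariates (plus an intercept) from columns of ``values``.

    ``values`` is (n_samples, k); ``covariates`` is (n_samples, c) or None.
    Uses the thin QR of the intercept-augmented covariate matrix, so applying
    the projection twice equals applying it once up to round-off.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    if covariates is None or (hasattr(covariates, "size") and np.size(covariates) == 0):
        design = np.ones((n, 1))
    else:
        covariates = np.asarray(covariates, dtype=float)
        if covariates.ndim == 1:
            covariates = covariates[:, None]
        design = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(design)
    return values - q @ (q.T @ values)


def bh_qvalues(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]
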