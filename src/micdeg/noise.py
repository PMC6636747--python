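"""White-noise injection at controlled signal-to-noise ratios.

Noise is zero-mean i.i.d. Gaussian.  The SNR is interpreted in decibels:
SNR = 10*log10(signal power / noise power), so SNR 0 means the injected
noise carries as much power as the signal itself and larger SNR means less
noise.  Signal power is measured per gene by default (the mean squared
deviation of the gene's values from its own mean), so weakly and strongly
expressed genes are degraded equally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .simulate import ExpressionDataset

__all__ = ["NoiseSpec", "add_white_noise", "noise_series", "DEFAULT_SNR_LEVELS"]

#: the benchmark noise ladder: SNR 0..10 dB in steps of 1
DEFAULT_SNR_LEVELS = tuple(range(0, 11))


@dataclass(frozen=True)
class NoiseSpec:
    snr_db: float
    power_scope: str = "per_gene"   # or "global"
    convention: str = "db"          # or "linear"

    def __post_init__(self):
        if self.power_scope not in ("per_gene", "global"):
            raise ValueError("power_scope must be 'per_gene' or 'global'")
        if self.convention not in ("db", "linear"):
            raise ValueError("convention must be 'db' or 'linear'")
        if self.convention == "linear" and self.snr_db <= 0:
            raise ValueError("linear SNR must be positive")


def _signal_power(matrix: np.ndarray, scope: str) -> np.ndarray:
    if scope == "per_gene":
        return matrix.var(axis=1, ddof=0)
    return np.full(matrix.shape[0], matrix.var(ddof=0))


def add_white_noise(dataset: ExpressionDataset, spec: NoiseSpec | float,
                    rng: np.random.Generator | int | None = None) -> ExpressionDataset:
    """Return a copy of ``dataset`` with white Gaussian noise added.

    Per-gene scope: gene j receives noise of variance P_j / 10**(snr_db/10)
    where P_j is gene j's signal power.  Zero-variance genes receive no
    noise (warned).  Phenotype and DE mask are unchanged.
    """
    if not isinstance(spec, NoiseSpec):
        spec = NoiseSpec(snr_db=float(spec))
    rng = np.random.default_rng(rng)
    power = _signal_power(dataset.matrix, spec.power_scope)
    if spec.convention == "db":
        ratio = 10.0 ** (spec.snr_db / 10.0)
    else:
        ratio = spec.snr_db
    noise_var = power / ratio
    zero = power == 0.0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} zero-variance gene(s) receive no noise")
        noise_var = np.where(zero, 0.0, noise_var)
    noise = rng.normal(0.0, 1.0, dataset.matrix.shape) * np.sqrt(noise_var)[:, None]
    return dataset.copy_with(matrix=dataset.matrix + noise)


def noise_series(dataset: ExpressionDataset, levels=DEFAULT_SNR_LEVELS,
                 base_seed: int = 0, power_scope: str = "per_gene"):
    """One independently noised copy of ``dataset`` per SNR level.

    Returns a list of (snr_db, noisy dataset) pairs; noise draws are
    independent across levels and deterministic in ``base_seed``.
    """
    levels = list(levels)
    if not levels:
        raise ValueError("levels must be nonempty")
    seeds = np.random.SeedSequence(base_seed).spawn(len(levels))
    return [
        (lvl, add_white_noise(dataset,
                              NoiseSpec(snr_db=lvl, power_scope=power_scope),
                              np.random.default_rng(s)))
        for lvl, s in zip(levels, seeds)
    ]
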