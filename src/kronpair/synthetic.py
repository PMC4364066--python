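"""Synthetic drug-target data with the structure the pair-kernel model assumes.

The generator draws latent factor vectors u_d, v_t of a chosen rank, builds
the drug and target kernels as the Gram matrices Kd = U U^T and
Kt = V V^T (symmetric PSD by construction), and sets the noiseless affinity
to the bilinear form truth(d, t) = u_d^T Sigma v_t for a fixed positive
diagonal Sigma.  Because the product pair kernel makes exactly this bilinear
class representable, the generator supports sharp recovery tests: at zero
noise the model class contains the truth.  Gaussian noise, uniform
missingness and binarization then emulate — at desk scale — the qualitative
features of quantitative kinase bioactivity matrices (complete Kd-style
panels, partially measured Ki-style panels, small binary benchmark sets).
This is a testing device, not a model of real kinase data: real similarity
matrices are not exact Gram factors of the label signal, and real
missingness is not uniform.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyDataError
from .io import InteractionTable, binarize
from .kernels import SimilarityMatrix

__all__ = ["SyntheticSpec", "generate", "make_fixture_like", "degrade"]


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic draw.

    ``latent_rank`` controls signal complexity (must not exceed either
    dimension); ``noise_sd`` is the SD of additive Gaussian noise on the
    labels; ``missing_fraction`` of entries are masked uniformly at random;
    an optional ``binarize_cutoff`` thresholds labels (above-cutoff =
    interaction, since generated labels are oriented larger-is-stronger).

    ``kernel_noise_sd`` corrupts the latent vectors used to build the
    kernels (but not the labels).  At 0 the kernels are perfect Gram
    factors of the signal and every experimental setting is equally easy;
    a positive value emulates realistic similarity matrices that capture
    label-relevant structure only partially, which is what makes predicting
    unseen drugs/targets genuinely harder than filling in missing entries.
    """

    n_drugs: int
    n_targets: int
    latent_rank: int = 2
    noise_sd: float = 0.0
    missing_fraction: float = 0.0
    binarize_cutoff: float | None = None
    seed: int = 0
    kernel_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_targets < 1:
            raise ValueError("n_drugs and n_targets must be positive")
        if not (1 <= self.latent_rank <= min(self.n_drugs, self.n_targets)):
            raise ValueError("latent_rank must be in [1, min(n_drugs, n_targets)]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        if self.kernel_noise_sd < 0:
            raise ValueError("kernel_noise_sd must be >= 0")


def _ids(prefix: str, n: int) -> list[str]:
    return [f"{prefix}{i:03d}" for i in range(n)]


def generate(
    spec: SyntheticSpec,
) -> tuple[SimilarityMatrix, SimilarityMatrix, InteractionTable, np.ndarray]:
    """Draw (Kd, Kt, table, truth) reproducibly from ``spec.seed``.

    All randomness flows through one seeded generator, so equal specs give
    bitwise-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    r = spec.latent_rank
    U = rng.standard_normal((spec.n_drugs, r))
    V = rng.standard_normal((spec.n_targets, r))
    # fixed positive diagonal weights, descending so factors are ordered
    sigma = np.linspace(1.5, 0.5, r)
    truth = (U * sigma) @ V.T
    labels = truth + spec.noise_sd * rng.standard_normal(truth.shape)
    mask = np.ones(truth.shape, dtype=bool)
    n_missing = int(round(spec.missing_fraction * truth.size))
    if n_missing:
        flat = rng.choice(truth.size, size=n_missing, replace=False)
        mask.flat[flat] = False
        labels = labels.copy()
        labels.flat[flat] = np.nan
    table = InteractionTable(
        _ids("D", spec.n_drugs),
        _ids("T", spec.n_targets),
        labels,
        mask,
        label_kind="quantitative",
        larger_is_stronger=True,
    )
    if spec.binarize_cutoff is not None:
        table = binarize(table, spec.binarize_cutoff, below_is_interaction=False)
    U_obs, V_obs = U, V
    if spec.kernel_noise_sd > 0:
        U_obs = U + spec.kernel_noise_sd * rng.standard_normal(U.shape)
        V_obs = V + spec.kernel_noise_sd * rng.standard_normal(V.shape)
    Kd = SimilarityMatrix(table.drug_ids, U_obs @ U_obs.T)
    Kt = SimilarityMatrix(table.target_ids, V_obs @ V_obs.T)
    return Kd, Kt, table, truth


#: documented fixed specs echoing the shapes of common benchmark panels at
#: reduced scale: a complete quantitative panel with more targets than
#: drugs, a partially measured panel with many more drugs than targets, and
#: a small binary set
_FIXTURES = {
    "kd-like": SyntheticSpec(20, 60, latent_rank=4, noise_sd=0.3, seed=20140409),
    "ki-like": SyntheticSpec(
        40, 12, latent_rank=3, noise_sd=0.3, missing_fraction=0.3, seed=20140410
    ),
    "nr-like": SyntheticSpec(
        12, 6, latent_rank=2, noise_sd=0.3, binarize_cutoff=1.0, seed=20140411
    ),
}


def make_fixture_like(
    name: str,
) -> tuple[SimilarityMatrix, SimilarityMatrix, InteractionTable]:
    """Fixed synthetic fixtures: ``kd-like``, ``ki-like`` or ``nr-like``."""
    try:
        spec = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; expected one of {sorted(_FIXTURES)}"
        ) from None
    Kd, Kt, table, _ = generate(spec)
    return Kd, Kt, table


def degrade(
    table: InteractionTable, missing_fraction: float, seed: int
) -> InteractionTable:
    """Mask ``round(fraction * n_measured)`` measured entries at random."""
    if not (0.0 <= missing_fraction < 1.0):
        raise ValueError("missing_fraction must be in [0, 1)")
    n_measured = table.n_measured
    n_mask = int(round(missing_fraction * n_measured))
    if n_mask >= n_measured:
        raise EmptyDataError("degrade would leave zero measured entries")
    if n_mask == 0:
        return InteractionTable(
            list(table.drug_ids),
            list(table.target_ids),
            table.labels.copy(),
            table.measured_mask.copy(),
            label_kind=table.label_kind,
            larger_is_stronger=table.larger_is_stronger,
        )
    rng = np.random.default_rng(seed)
    pairs = table.measured_pairs()
    chosen = rng.choice(len(pairs), size=n_mask, replace=False)
    labels = table.labels.copy()
    mask = table.measured_mask.copy()
    for idx in chosen:
        d, t = pairs[idx]
        mask[d, t] = False
        labels[d, t] = np.nan
    return InteractionTable(
        list(table.drug_ids),
        list(table.target_ids),
        labels,
        mask,
        label_kind=table.label_kind,
        larger_is_stronger=table.larger_is_stronger,
    )
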