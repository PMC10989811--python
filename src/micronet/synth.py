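"""Synthetic abundance tables with planted modular correlation structure.

The generator follows a Gaussian-copula-then-Poisson scheme: per sample a
latent Gaussian value is drawn for every taxon, correlated within planted
modules through shared module factors; latent values are pushed through a
per-sample softmax into relative abundances and observed as Poisson counts
at a given mean sequencing depth.  The softmax makes the counts
compositional, which is the regime the SparCC estimator is designed for.

Reproducibility: every operation draws from its own
``numpy.random.default_rng([seed, label])`` PCG64 stream, with a fixed
integer label per operation (abundance = 1, bipartite = 2), so adding
operations never perturbs existing fixtures.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io_tables import AbundanceTable

_STREAM_ABUNDANCE = 1
_STREAM_BIPARTITE = 2


@dataclasses.dataclass
class SynthSpec:
    """Parameters of the planted-module abundance generator.

    rho_in / rho_out are the within-module / between-module latent
    correlations (requires 0 <= rho_out < rho_in <= 1); noise_sd scales the
    idiosyncratic Gaussian noise (latent correlations equal rho_in / rho_out
    exactly when noise_sd = 1); depth is the mean sequencing depth per
    sample.
    """

    n_taxa: int = 60
    n_samples: int = 50
    n_modules: int = 4
    rho_in: float = 0.8
    rho_out: float = 0.0
    noise_sd: float = 1.0
    depth: float = 10_000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho_out < self.rho_in <= 1.0 and not (
                self.rho_in == 0.0 and self.rho_out == 0.0):
            raise ValueError(
                f"need 0 <= rho_out < rho_in <= 1, got "
                f"rho_in={self.rho_in}, rho_out={self.rho_out}")
        if self.n_modules > self.n_taxa:
            raise ValueError("n_modules cannot exceed n_taxa")


def _latent_matrix(spec: SynthSpec, modules: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    """Taxon-by-sample latent Gaussian values with planted correlation."""
    global_f = rng.standard_normal(spec.n_samples)
    module_f = rng.standard_normal((spec.n_modules, spec.n_samples))
    noise = rng.standard_normal((spec.n_taxa, spec.n_samples))
    z = (np.sqrt(spec.rho_out) * global_f
         + np.sqrt(spec.rho_in - spec.rho_out) * module_f[modules]
         + np.sqrt(1.0 - spec.rho_in) * spec.noise_sd * noise)
    return z


def _poissonize(z: np.ndarray, depth: float, n_samples: int,
                rng: np.random.Generator) -> np.ndarray:
    expz = np.exp(z - z.max(axis=0, keepdims=True))
    frac = expz / expz.sum(axis=0, keepdims=True)
    return rng.poisson(depth * frac).astype(float)


def simulate_abundance(spec: SynthSpec) -> tuple[AbundanceTable, pd.Series]:
    """Generate an abundance table plus the planted module labels.

    Taxa are split into ``n_modules`` contiguous near-equal blocks; each
    block shares one latent factor per sample.  Returns the table and a
    taxon-indexed Series of true module labels.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_ABUNDANCE])
    taxa = [f"t{i + 1:03d}" for i in range(spec.n_taxa)]
    samples = [f"s{i + 1:03d}" for i in range(spec.n_samples)]
    blocks = np.array_split(np.arange(spec.n_taxa), spec.n_modules)
    modules = np.empty(spec.n_taxa, dtype=int)
    for k, block in enumerate(blocks):
        modules[block] = k
    z = _latent_matrix(spec, modules, rng)
    counts = _poissonize(z, spec.depth, spec.n_samples, rng)
    table = AbundanceTable(values=pd.DataFrame(counts, index=taxa,
                                               columns=samples))
    truth = pd.Series([f"M{m + 1}" for m in modules],
                      index=pd.Index(taxa, name="taxon"), name="module")
    return table, truth


def simulate_latents(spec: SynthSpec) -> tuple[np.ndarray, np.ndarray]:
    """Latent Gaussian matrix and module assignment (no Poisson stage).

    Exposes the copula layer so tests can check the planted correlation
    structure directly.
    """
    rng = np.random.default_rng([spec.seed, _STREAM_ABUNDANCE])
    blocks = np.array_split(np.arange(spec.n_taxa), spec.n_modules)
    modules = np.empty(spec.n_taxa, dtype=int)
    for k, block in enumerate(blocks):
        modules[block] = k
    return _latent_matrix(spec, modules, rng), modules


def simulate_bipartite(
    spec: SynthSpec,
    group_sizes: tuple[int, int] = (10, 10),
    n_pairs: int = 5,
) -> tuple[AbundanceTable, list[tuple[str, str]]]:
    """Two-group abundance table with correlated pairs planted across groups.

    Taxa split into groups A and B of the given sizes; ``n_pairs`` pairs
    (a_i, b_i) share a latent factor at correlation ``rho_in``; all other
    taxa are independent.  No within-group correlation is planted, so the
    bipartite restriction can never mask a planted pair.  Returns the
    table (carrying group labels) and the planted cross-group pairs.
    """
    n_a, n_b = group_sizes
    if n_pairs > min(n_a, n_b):
        raise ValueError("n_pairs cannot exceed the smaller group size")
    rng = np.random.default_rng([spec.seed, _STREAM_BIPARTITE])
    n_taxa = n_a + n_b
    taxa = [f"a{i + 1:03d}" for i in range(n_a)] + \
           [f"b{i + 1:03d}" for i in range(n_b)]
    samples = [f"s{i + 1:03d}" for i in range(spec.n_samples)]
    shared = rng.standard_normal((n_pairs, spec.n_samples))
    noise = rng.standard_normal((n_taxa, spec.n_samples))
    z = spec.noise_sd * noise
    for p in range(n_pairs):
        for row in (p, n_a + p):  # a_{p+1} paired with b_{p+1}
            z[row] = (np.sqrt(spec.rho_in) * shared[p]
                      + np.sqrt(1.0 - spec.rho_in) * spec.noise_sd * noise[row])
    counts = _poissonize(z, spec.depth, spec.n_samples, rng)
    group = {t: ("A" if t.startswith("a") else "B") for t in taxa}
    table = AbundanceTable(
        values=pd.DataFrame(counts, index=taxa, columns=samples), group=group)
    pairs = [(f"a{p + 1:03d}", f"b{p + 1:03d}") for p in range(n_pairs)]
    return table, pairs
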