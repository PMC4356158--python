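"""Synthetic fitness-record collections with a known adaptability structure.

The generator inverts the standardization + log-log model: per-generation
initial deficits |x_i| are drawn uniformly on a range (one genotype pinned at
deficit 0 as the reference), expected excess gains follow the power law
E[y_i] = gain_scale * |x_i|**true_beta, lognormal measurement noise of the
requested standard deviation perturbs ln(y), and the (x, y) coordinates are
converted back to raw initial/final fitness values over the requested number
of generations.  With noise_sd = 0 the round trip standardize(generate(...))
recovers the generating coordinates exactly.

Study presets mirror the designs of published founder collections (numbers
of genotypes and generation spans); their deficit ranges and noise levels
are structural defaults, not quantitative mimics of any real dataset.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .standardization import FitnessRecord


@dataclass(frozen=True)
class StudyPreset:
    """Shape of one experimental founder collection."""

    name: str
    n_genotypes: int
    generations: int
    deficit_range: tuple[float, float]
    noise_sd: float
    default_beta: float = 0.8
    description: str = ""

    def __post_init__(self) -> None:
        if self.n_genotypes < 2:
            raise InputError(f"n_genotypes must be >= 2, got {self.n_genotypes}")
        if self.generations < 1:
            raise InputError(f"generations must be >= 1, got {self.generations}")
        lo, hi = self.deficit_range
        if lo < 0 or hi <= lo:
            raise InputError(f"deficit_range must satisfy 0 <= min < max, got {self.deficit_range}")


STUDY_PRESETS: dict[str, StudyPreset] = {
    p.name: p
    for p in (
        StudyPreset(
            "yeastdel187", 187, 400, (0.0, 0.004), 0.35,
            description="yeast single-gene deletion strains with graded growth defects",
        ),
        StudyPreset(
            "ydiv250", 64, 250, (0.0002, 0.002), 0.2,
            description="yeast lines adaptively diverged before the experiment, 250 generations",
        ),
        StudyPreset(
            "ydiv500", 64, 500, (0.0002, 0.002), 0.2,
            description="the same divergent-founder design measured at 500 generations",
        ),
        StudyPreset(
            "rif8", 8, 300, (0.0003, 0.003), 0.15,
            description="rifampicin-resistant point mutants with costly resistance",
        ),
        StudyPreset(
            "mutator23", 23, 640, (0.0005, 0.005), 0.3, default_beta=1.2,
            description="hypermutator lineages degraded by bottleneck mutation accumulation "
            "(steep adaptability emulated via a larger default exponent)",
        ),
        StudyPreset(
            "phage8", 8, 240, (0.0005, 0.005), 0.15,
            description="microvirid phage strains of graded infection efficiency",
        ),
    )
}


def generate_collection(
    n_genotypes: int,
    deficit_range: tuple[float, float],
    true_beta: float,
    gain_scale: float = 1.0,
    noise_sd: float = 0.0,
    generations: int = 250,
    seed: int | None = None,
    reference_gain: float | None = None,
    scale: str = "relative",
) -> list[FitnessRecord]:
    """Draw a founder collection whose standardized points follow a known power law.

    Parameters
    ----------
    n_genotypes
        Collection size, including the reference pinned at deficit 0.
    deficit_range
        (min, max) per-generation initial log-deficit magnitudes |x|.
    true_beta
        Generating log-log slope: E[y] = gain_scale * |x|**true_beta.
    gain_scale
        Prefactor of the power law, natural-log units per generation.
    noise_sd
        Standard deviation of Gaussian noise added to ln(y) of non-reference
        genotypes (lognormal multiplicative noise on the excess gain).
    generations
        Elapsed generations G used to convert (x, y) back to fitness values.
    seed
        Mandatory RNG seed.
    reference_gain
        Per-generation log gain of the reference genotype itself; defaults
        to the power-law prediction at the lower edge of ``deficit_range``
        (0 when the range starts at 0).
    """
    if n_genotypes < 2:
        raise InputError(f"n_genotypes must be >= 2, got {n_genotypes}")
    lo, hi = deficit_range
    if lo < 0 or hi < lo:
        raise InputError(f"deficit_range must satisfy 0 <= min <= max, got {deficit_range}")
    if true_beta <= 0:
        raise InputError(f"true_beta must be > 0, got {true_beta}")
    if noise_sd < 0:
        raise InputError(f"noise_sd must be >= 0, got {noise_sd}")
    if seed is None:
        raise InputError("an RNG seed is mandatory")
    rng = np.random.default_rng(seed)

    if reference_gain is None:
        reference_gain = gain_scale * lo**true_beta if lo > 0 else 0.0

    deficits = rng.uniform(lo, hi, size=n_genotypes - 1)
    width = len(str(n_genotypes - 1))
    records = [
        FitnessRecord(
            genotype_id="g" + "0" * width,
            w_start=1.0,
            w_final=math.exp(generations * reference_gain),
            generations=generations,
            scale=scale,
        )
    ]
    noise = rng.normal(0.0, noise_sd, size=n_genotypes - 1) if noise_sd > 0 else np.zeros(n_genotypes - 1)
    for i, (d, eps) in enumerate(zip(deficits, noise), start=1):
        x = -d
        y = gain_scale * d**true_beta * math.exp(eps) if d > 0 else 0.0
        w_start = math.exp(generations * x)
        w_final = w_start * math.exp(generations * (y + reference_gain))
        records.append(
            FitnessRecord(
                genotype_id=f"g{i:0{width}d}",
                w_start=w_start,
                w_final=w_final,
                generations=generations,
                scale=scale,
            )
        )
    return records


def emulate_study(
    preset_name: str, true_beta: float | None = None, seed: int | None = None
) -> list[FitnessRecord]:
    """Generate a collection shaped like one of the study presets."""
    if preset_name not in STUDY_PRESETS:
        raise InputError(
            f"unknown preset {preset_name!r}; available: {sorted(STUDY_PRESETS)}"
        )
    p = STUDY_PRESETS[preset_name]
    return generate_collection(
        n_genotypes=p.n_genotypes,
        deficit_range=p.deficit_range,
        true_beta=p.default_beta if true_beta is None else true_beta,
        noise_sd=p.noise_sd,
        generations=p.generations,
        seed=seed,
    )
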