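"""Standardization of heterogeneous fitness measurements.

Evolution experiments report fitness on different scales (relative fitness
from competition assays, growth-rate ratios, exponentiated Malthusian
differences) and run for different numbers of generations.  To compare
declining-adaptability patterns across datasets, every measurement is first
mapped onto a common multiplicative per-generation scale (whose natural log
is a Malthusian difference per generation) and then expressed relative to
the fittest founder of the collection:

    x_i = ln(w_i_start / w_ref_start) / G      (initial log deficit per generation)
    y_i = [ln(w_i_final / w_i_start)
           - ln(w_ref_final / w_ref_start)] / G  (excess log gain per generation)

where the reference genotype is the one with the highest starting fitness.
By construction the reference maps to (0, 0), and both coordinates are
invariant under rescaling every fitness in the collection by a positive
constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .errors import DomainError, InputError

VALID_SCALES = ("relative", "growth_rate_ratio", "malthusian_exp")


@dataclass(frozen=True)
class FitnessRecord:
    """One genotype's initial/final fitness over an evolution experiment.

    Parameters
    ----------
    genotype_id
        Text label, unique within a collection.
    w_start, w_final
        Initial and final fitness, strictly positive, on the declared scale.
    generations
        Elapsed generations of the evolution experiment (>= 1).
    scale
        How fitness was measured: ``relative`` (per-generation multiplier),
        ``growth_rate_ratio`` (ratio accumulated over a multi-generation
        assay) or ``malthusian_exp`` (e raised to a per-generation
        Malthusian difference; numerically an identity transform).
    """

    genotype_id: str
    w_start: float
    w_final: float
    generations: int
    scale: str = "relative"

    def __post_init__(self) -> None:
        if self.w_start <= 0 or self.w_final <= 0:
            raise DomainError(
                f"fitness must be > 0, got w_start={self.w_start}, "
                f"w_final={self.w_final} for {self.genotype_id!r}"
            )
        if self.generations < 1:
            raise InputError(f"generations must be >= 1, got {self.generations}")
        if self.scale not in VALID_SCALES:
            raise InputError(
                f"unknown fitness scale {self.scale!r}; expected one of {VALID_SCALES}"
            )


@dataclass(frozen=True)
class StandardizedPoint:
    """Per-generation standardized coordinates of one genotype.

    ``x`` is the initial log deficit versus the fittest founder (<= 0 when
    the founder ladder is anchored at the top), ``y`` the excess log gain,
    both in natural-log fitness units per generation.
    """

    genotype_id: str
    x: float
    y: float
    is_reference: bool = False


def to_malthusian(value: float, scale: str, assay_generations: float = 1.0) -> float:
    """Convert a fitness value to the common per-generation multiplicative scale.

    Relative-fitness and exponentiated-Malthusian inputs are already
    per-generation multipliers (identity transform).  Growth-rate-ratio
    inputs accumulated over a multi-generation assay are taken to the power
    ``1/assay_generations``.
    """
    if value <= 0:
        raise DomainError(f"fitness must be > 0, got {value}")
    if assay_generations <= 0:
        raise InputError(f"assay_generations must be > 0, got {assay_generations}")
    if scale in ("relative", "malthusian_exp"):
        return float(value)
    if scale == "growth_rate_ratio":
        return float(value ** (1.0 / assay_generations))
    raise InputError(f"unknown fitness scale {scale!r}; expected one of {VALID_SCALES}")


def select_reference(records: list[FitnessRecord]) -> str:
    """Return the genotype_id of the fittest founder.

    Ties on starting fitness break toward the lexicographically smallest id,
    so the choice is deterministic.
    """
    if not records:
        raise InputError("cannot select a reference from an empty collection")
    best = min(records, key=lambda r: (-r.w_start, r.genotype_id))
    return best.genotype_id


def standardize(
    records: list[FitnessRecord],
    generations: int | None = None,
    assay_generations: float = 1.0,
    x_from_final: bool = False,
) -> list[StandardizedPoint]:
    """Compute per-generation (x, y) coordinates against the fittest founder.

    Parameters
    ----------
    records
        Non-empty collection of :class:`FitnessRecord`.
    generations
        Collection-level override of the per-record generation counts.
    assay_generations
        Span of the fitness assay, used only for ``growth_rate_ratio`` inputs.
    x_from_final
        If True, compute the initial ratio from the genotype's *final*
        fitness (x_i = ln(w_i_final / w_ref_start) / G).  This alternative
        convention is exposed for comparison only; the default uses the
        starting fitness, which anchors the reference at (0, 0).
    """
    if not records:
        raise InputError("cannot standardize an empty collection")
    if generations is not None and generations <= 0:
        raise InputError(f"generations override must be > 0, got {generations}")

    ref_id = select_reference(records)
    ref = next(r for r in records if r.genotype_id == ref_id)

    def conv(rec: FitnessRecord) -> tuple[float, float]:
        return (
            to_malthusian(rec.w_start, rec.scale, assay_generations),
            to_malthusian(rec.w_final, rec.scale, assay_generations),
        )

    ws_ref, wf_ref = conv(ref)
    ref_gain = math.log(wf_ref / ws_ref)

    points = []
    for rec in records:
        g = generations if generations is not None else rec.generations
        ws, wf = conv(rec)
        x_num = math.log(wf / ws_ref) if x_from_final else math.log(ws / ws_ref)
        y_num = math.log(wf / ws) - ref_gain
        points.append(
            StandardizedPoint(
                genotype_id=rec.genotype_id,
                x=x_num / g,
                y=y_num / g,
                is_reference=rec.genotype_id == ref_id,
            )
        )
    return points


# ---------------------------------------------------------------------------
# Tabular I/O (TSV/CSV with a header row; '#' starts a comment line)
# ---------------------------------------------------------------------------

_REQUIRED_COLUMNS = ("genotype_id", "w_start", "w_final", "generations", "scale")


def read_fitness_table(path) -> list[FitnessRecord]:
    """Read fitness records from a TSV/CSV file (delimiter auto-detected)."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in _REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"fitness table {path} is missing columns: {missing}")
    return [
        FitnessRecord(
            genotype_id=str(row.genotype_id),
            w_start=float(row.w_start),
            w_final=float(row.w_final),
            generations=int(row.generations),
            scale=str(row.scale),
        )
        for row in df.itertuples(index=False)
    ]


def write_fitness_table(records: list[FitnessRecord], path) -> None:
    pd.DataFrame(
        {
            "genotype_id": [r.genotype_id for r in records],
            "w_start": [r.w_start for r in records],
            "w_final": [r.w_final for r in records],
            "generations": [r.generations for r in records],
            "scale": [r.scale for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def read_points_table(path) -> list[StandardizedPoint]:
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    missing = [c for c in ("genotype_id", "x", "y") if c not in df.columns]
    if missing:
        raise InputError(f"points table {path} is missing columns: {missing}")
    flags = df["reference_flag"] if "reference_flag" in df.columns else [False] * len(df)
    return [
        StandardizedPoint(str(g), float(x), float(y), bool(f))
        for g, x, y, f in zip(df["genotype_id"], df["x"], df["y"], flags)
    ]


def write_points_table(points: list[StandardizedPoint], path) -> None:
    pd.DataFrame(
        {
            "genotype_id": [p.genotype_id for p in points],
            "x": [p.x for p in points],
            "y": [p.y for p in points],
            "reference_flag": [p.is_reference for p in points],
        }
    ).to_csv(path, sep="\t", index=False)
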