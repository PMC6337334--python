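"""The stage-specificity screen.

For each gene a reference level ``R`` is computed over the reference-group
samples (max by default; min and mean are available to probe how sensitive
the selection is to that reading).  The gene is selected as
reference-stage-specific iff ``R > 0`` and

* every strict-group sample has RPKM strictly below ``strict_threshold * R``
  (default: below 20% of the reference level), and
* every relaxed-group sample has RPKM strictly below
  ``relaxed_threshold * R`` (default: below 70%).

Both comparisons are strict (<), so a sample sitting exactly at the bound
rejects the gene, and they are made in raw double precision with no epsilon:
the thresholds are exact decimal fractions of data values and an epsilon
would introduce hidden nondeterminism at boundaries.

Results are returned for all genes, selected or not, with per-group worst
ratios and the first failing group, so near-misses remain inspectable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from stagespec.expression import ExpressionMatrix, GroupScheme


class ScreenError(ValueError):
    """Raised when the scheme and matrix cannot be screened together."""


@dataclass(frozen=True)
class ScreenResult:
    """Per-gene verdict with diagnostics.

    ``worst_ratio_per_group`` maps each non-reference group to
    ``max(sample RPKM) / R``; entries are NaN when ``R == 0``.
    ``first_failing_group`` is the first group, in scheme order, containing
    a sample at or above its bound (None for selected genes; the string
    "reference" when the gene failed because ``R == 0``).
    """

    gene_id: str
    selected: bool
    reference_level: float
    worst_ratio_per_group: Mapping[str, float]
    first_failing_group: str | None


@dataclass(frozen=True)
class ScreenSummary:
    """Counts over a full screen run."""

    n_genes_total: int
    n_selected: int
    fraction_selected: float  # NaN when n_genes_total == 0
    strict_threshold: float
    relaxed_threshold: float
    reference_stat: str
    first_failures_per_group: Mapping[str, int]


class ScreenResults(Sequence):
    """Ordered collection of :class:`ScreenResult`, one per gene.

    Behaves as a sequence and additionally offers tabular export
    (:meth:`to_frame`), the selected subset (:meth:`selected_ids`) and the
    run summary (:meth:`summary`).
    """

    def __init__(self, results: list[ScreenResult], scheme: GroupScheme):
        self._results = results
        self._scheme = scheme

    def __len__(self) -> int:
        return len(self._results)

    def __getitem__(self, idx):
        return self._results[idx]

    def __iter__(self) -> Iterator[ScreenResult]:
        return iter(self._results)

    @property
    def scheme(self) -> GroupScheme:
        return self._scheme

    def selected_ids(self) -> list[str]:
        return [r.gene_id for r in self._results if r.selected]

    def summary(self) -> ScreenSummary:
        return summarize(self)

    def to_frame(self) -> pd.DataFrame:
        """One row per gene: verdict, reference level, per-group worst ratios."""
        group_names = [g.name for g in self._scheme.comparison_groups]
        rows = []
        for r in self._results:
            row = {
                "gene_id": r.gene_id,
                "selected": r.selected,
                "reference_level": r.reference_level,
            }
            for name in group_names:
                row[f"ratio_{name}"] = r.worst_ratio_per_group.get(name, math.nan)
            row["first_failing_group"] = r.first_failing_group or ""
            rows.append(row)
        columns = (
            ["gene_id", "selected", "reference_level"]
            + [f"ratio_{n}" for n in group_names]
            + ["first_failing_group"]
        )
        return pd.DataFrame(rows, columns=columns)


def _check_scheme_against_matrix(
    matrix: ExpressionMatrix, scheme: GroupScheme
) -> None:
    missing = [s for s in scheme.all_samples() if s not in matrix.values.columns]
    if missing:
        raise ScreenError(
            f"scheme samples absent from matrix: {', '.join(missing)}"
        )


def _reference_levels(
    matrix: ExpressionMatrix, scheme: GroupScheme
) -> np.ndarray:
    ref = matrix.values[list(scheme.reference_samples)].to_numpy()
    if scheme.reference_stat == "max":
        return ref.max(axis=1)
    if scheme.reference_stat == "min":
        return ref.min(axis=1)
    return ref.mean(axis=1)


def screen(matrix: ExpressionMatrix, scheme: GroupScheme) -> ScreenResults:
    """Apply the ratio-threshold screen to every gene.

    Raises :class:`ScreenError` if any scheme sample is absent from the
    matrix.  An empty matrix yields an empty result.
    """
    _check_scheme_against_matrix(matrix, scheme)
    n = matrix.n_genes
    if n == 0:
        return ScreenResults([], scheme)

    R = _reference_levels(matrix, scheme)
    groups = scheme.comparison_groups
    group_max = {
        g.name: matrix.values[list(g.samples)].to_numpy().max(axis=1)
        for g in groups
    }

    # A per-sample comparison rpkm(s) < t*R within a group is equivalent to
    # comparing the group max, since the threshold is constant in the group.
    passes = R > 0.0
    fail_mask = {}
    for g in groups:
        t = scheme.threshold_for(g)
        fails = ~(group_max[g.name] < t * R)
        fail_mask[g.name] = fails
        passes &= ~fails

    gene_ids = matrix.gene_ids
    results: list[ScreenResult] = []
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ratios = {
            name: np.where(R > 0.0, gm / R, np.nan)
            for name, gm in group_max.items()
        }
    for i, gene_id in enumerate(gene_ids):
        if passes[i]:
            failing = None
        elif R[i] <= 0.0:
            failing = "reference"
        else:
            failing = next(g.name for g in groups if fail_mask[g.name][i])
        results.append(
            ScreenResult(
                gene_id=gene_id,
                selected=bool(passes[i]),
                reference_level=float(R[i]),
                worst_ratio_per_group={
                    g.name: float(ratios[g.name][i]) for g in groups
                },
                first_failing_group=failing,
            )
        )
    return ScreenResults(results, scheme)


def screen_oracle(matrix: ExpressionMatrix, scheme: GroupScheme) -> ScreenResults:
    """Naive per-gene, per-sample reference implementation of :func:`screen`.

    Pure-Python loops, written independently of the vectorized path; used in
    tests as the ground-truth oracle.  Quadratic and intended for small
    matrices only.
    """
    _check_scheme_against_matrix(matrix, scheme)
    frame = matrix.values
    results: list[ScreenResult] = []
    for gene_id in matrix.gene_ids:
        ref_values = [float(frame.at[gene_id, s]) for s in scheme.reference_samples]
        if scheme.reference_stat == "max":
            R = max(ref_values)
        elif scheme.reference_stat == "min":
            R = min(ref_values)
        else:
            R = sum(ref_values) / len(ref_values)

        worst: dict[str, float] = {}
        failing: str | None = None
        selected = R > 0.0
        if not selected:
            failing = "reference"
        for group in scheme.comparison_groups:
            threshold = scheme.threshold_for(group)
            group_worst = math.nan
            for sample in group.samples:
                value = float(frame.at[gene_id, sample])
                if R > 0.0:
                    ratio = value / R
                    if math.isnan(group_worst) or ratio > group_worst:
                        group_worst = ratio
                if R > 0.0 and not (value < threshold * R):
                    if selected:
                        selected = False
                        failing = group.name
            worst[group.name] = group_worst
        results.append(
            ScreenResult(
                gene_id=gene_id,
                selected=selected,
                reference_level=R,
                worst_ratio_per_group=worst,
                first_failing_group=None if selected else failing,
            )
        )
    return ScreenResults(results, scheme)


def summarize(results: ScreenResults) -> ScreenSummary:
    """Counts, selected fraction and first-failure tally for a screen run."""
    n_total = len(results)
    n_selected = sum(1 for r in results if r.selected)
    fraction = n_selected / n_total if n_total else math.nan
    failures: dict[str, int] = {}
    for r in results:
        if r.first_failing_group:
            failures[r.first_failing_group] = (
                failures.get(r.first_failing_group, 0) + 1
            )
    scheme = results.scheme
    return ScreenSummary(
        n_genes_total=n_total,
        n_selected=n_selected,
        fraction_selected=fraction,
        strict_threshold=scheme.strict_threshold,
        relaxed_threshold=scheme.relaxed_threshold,
        reference_stat=scheme.reference_stat,
        first_failures_per_group=failures,
    )


def write_screen_results(
    results: ScreenResults, path, *, selected_only: bool = False
) -> None:
    """Write screen results as TSV (gene, verdict, level, ratios, failure)."""
    frame = results.to_frame()
    if selected_only:
        frame = frame[frame["selected"]]
    frame.to_csv(path, sep="\t", index=False)


def compare_reference_stats(
    matrix: ExpressionMatrix, scheme: GroupScheme
) -> pd.DataFrame:
    """Diagnose how the reference-statistic reading changes the selection.

    Runs the screen under each supported reference statistic (max, min,
    mean) and reports the selected count and the genes whose verdict differs
    from the scheme's configured statistic.  Useful for localizing which
    interpretation choice accounts for a count deviating from an expected
    value.
    """
    from stagespec.expression import REFERENCE_STATS

    base = set(screen(matrix, scheme).selected_ids())
    rows = []
    for stat in REFERENCE_STATS:
        sel = set(screen(matrix, scheme.replace(reference_stat=stat)).selected_ids())
        rows.append(
            {
                "reference_stat": stat,
                "n_selected": len(sel),
                "gained_vs_configured": ",".join(sorted(sel - base)),
                "lost_vs_configured": ",".join(sorted(base - sel)),
            }
        )
    return pd.DataFrame(rows)
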