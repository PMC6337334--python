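"""Synthetic expression matrices and companion files with planted truth.

The generator emulates the shape of a developmental RPKM table — by default
49 samples: 2 reference (pediveliger-like, P1/P2), 2 relaxed (late-umbo-like,
LU1/LU2) and 45 strict (other stages and adult organs) — and plants three
gene populations:

* **background** genes draw a per-gene log-normal base level shared across
  all samples, with multiplicative log-normal sample noise, so their
  expression is broad and they rarely pass the screen;
* **planted specific** genes draw a reference level ``R >= 1`` and every
  non-reference sample uniformly below ``threshold / m * R``, where the
  margin ``m > 1`` controls how far inside the bound they sit — they pass
  the screen by construction;
* **planted near-miss** genes are built like specific genes except exactly
  one strict sample is placed at ``strict_threshold * R * m``, above the
  bound, so they fail exactly one condition and must never be selected.

All draws come from one seeded generator, and emitted values are rounded to
a fixed decimal grid (six decimals, rounding planted values toward zero so
the bound cannot be crossed), making output reproducible across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from stagespec.annotations import COMPARTMENTS
from stagespec.composition import STANDARD_RESIDUES
from stagespec.expression import ExpressionMatrix, GroupScheme, SampleGroup
from stagespec.screen import ScreenResults


class SimulationError(ValueError):
    """Raised for invalid generation parameters."""


@dataclass(frozen=True)
class SimulationParams:
    """Generation parameters; defaults mirror the 49-sample study design."""

    n_genes: int = 1000
    n_specific: int = 50
    n_near_miss: int = 20
    n_reference: int = 2
    n_relaxed: int = 2
    n_strict: int = 45
    margin: float = 10.0
    strict_threshold: float = 0.20
    relaxed_threshold: float = 0.70
    background_log_mean: float = 1.0
    background_log_sigma: float = 1.5
    noise_sigma: float = 0.5

    def __post_init__(self) -> None:
        if self.margin <= 1.0:
            raise SimulationError(f"margin must exceed 1, got {self.margin}")
        if self.n_reference < 1:
            raise SimulationError("need at least one reference sample")
        if self.n_relaxed < 0 or self.n_strict < 1:
            raise SimulationError("need non-negative relaxed and >=1 strict samples")
        if self.n_specific + self.n_near_miss > self.n_genes:
            raise SimulationError("planted genes exceed n_genes")

    @property
    def reference_samples(self) -> tuple[str, ...]:
        return tuple(f"P{i + 1}" for i in range(self.n_reference))

    @property
    def relaxed_samples(self) -> tuple[str, ...]:
        return tuple(f"LU{i + 1}" for i in range(self.n_relaxed))

    @property
    def strict_samples(self) -> tuple[str, ...]:
        return tuple(f"S{i + 1}" for i in range(self.n_strict))

    def make_scheme(self) -> GroupScheme:
        groups = [
            SampleGroup("pediveliger", self.reference_samples, "reference")
        ]
        if self.n_relaxed:
            groups.append(
                SampleGroup("late_umbo", self.relaxed_samples, "relaxed")
            )
        groups.append(SampleGroup("other", self.strict_samples, "strict"))
        return GroupScheme(
            groups=tuple(groups),
            strict_threshold=self.strict_threshold,
            relaxed_threshold=self.relaxed_threshold,
        )


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for recovery scoring."""

    planted_specific: frozenset[str]
    planted_near_miss: frozenset[str]
    params: SimulationParams
    seed: int

    @property
    def background(self) -> int:
        return (
            self.params.n_genes
            - len(self.planted_specific)
            - len(self.planted_near_miss)
        )


@dataclass(frozen=True)
class RecoveryMetrics:
    """Screen performance against planted truth."""

    sensitivity: float  # NaN when no specific genes were planted
    near_miss_hits: int
    background_false_positive_rate: float  # NaN when no background genes


def _grid(values: np.ndarray) -> np.ndarray:
    """Round toward zero onto a 1e-6 grid (never crosses an upper bound)."""
    return np.floor(values * 1e6) / 1e6


def generate_matrix(
    params: SimulationParams = SimulationParams(), seed: int = 0
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate a seeded synthetic RPKM matrix with planted truth.

    Gene order is shuffled so planted genes are not positionally
    identifiable; the truth object records their IDs.
    """
    rng = np.random.default_rng(seed)
    p = params
    samples = list(p.reference_samples + p.relaxed_samples + p.strict_samples)
    n_samples = len(samples)
    n_background = p.n_genes - p.n_specific - p.n_near_miss

    rows: list[np.ndarray] = []
    gene_ids: list[str] = []

    # Background: per-gene base level shared across samples + sample noise.
    base = rng.lognormal(p.background_log_mean, p.background_log_sigma, n_background)
    noise = rng.lognormal(0.0, p.noise_sigma, (n_background, n_samples))
    background_values = _grid(base[:, None] * noise)
    for i in range(n_background):
        gene_ids.append(f"SYN_BG_{i + 1:05d}")
        rows.append(background_values[i])

    def planted_row(R: float, near_miss_sample: int | None) -> np.ndarray:
        row = np.empty(n_samples)
        # Reference samples: first carries R so max over references is R.
        row[0] = R
        for j in range(1, p.n_reference):
            row[j] = _grid(np.array([rng.uniform(0.5, 1.0) * R]))[0]
        col = p.n_reference
        for _ in p.relaxed_samples:
            bound = p.relaxed_threshold / p.margin * R
            row[col] = _grid(np.array([rng.uniform(0.0, bound)]))[0]
            col += 1
        for _ in p.strict_samples:
            bound = p.strict_threshold / p.margin * R
            row[col] = _grid(np.array([rng.uniform(0.0, bound)]))[0]
            col += 1
        if near_miss_sample is not None:
            # Exactly one strict sample at threshold * R * margin: above the
            # bound, so exactly one condition fails.
            row[p.n_reference + p.n_relaxed + near_miss_sample] = (
                p.strict_threshold * R * p.margin
            )
        return row

    specific_ids = []
    for i in range(p.n_specific):
        gene_id = f"SYN_SPEC_{i + 1:05d}"
        R = round(float(rng.uniform(1.0, 200.0)), 3)
        gene_ids.append(gene_id)
        rows.append(planted_row(R, None))
        specific_ids.append(gene_id)

    near_miss_ids = []
    for i in range(p.n_near_miss):
        gene_id = f"SYN_NEAR_{i + 1:05d}"
        R = round(float(rng.uniform(1.0, 200.0)), 3)
        which = int(rng.integers(0, p.n_strict))
        gene_ids.append(gene_id)
        rows.append(planted_row(R, which))
        near_miss_ids.append(gene_id)

    order = rng.permutation(len(gene_ids))
    frame = pd.DataFrame(
        np.vstack(rows)[order],
        index=pd.Index([gene_ids[i] for i in order], name="gene_id"),
        columns=samples,
    )
    matrix = ExpressionMatrix(frame)
    truth = SyntheticTruth(
        planted_specific=frozenset(specific_ids),
        planted_near_miss=frozenset(near_miss_ids),
        params=p,
        seed=seed,
    )
    return matrix, truth


def recovery_metrics(
    results: ScreenResults, truth: SyntheticTruth
) -> RecoveryMetrics:
    """Score a screen run against planted truth.

    Raises ``SimulationError`` if any truth gene is absent from the results.
    """
    verdicts = {r.gene_id: r.selected for r in results}
    missing = (truth.planted_specific | truth.planted_near_miss) - set(verdicts)
    if missing:
        raise SimulationError(
            f"truth genes missing from results: {sorted(missing)[:5]}"
        )
    if truth.planted_specific:
        sensitivity = sum(
            1 for g in truth.planted_specific if verdicts[g]
        ) / len(truth.planted_specific)
    else:
        sensitivity = math.nan
    near_hits = sum(1 for g in truth.planted_near_miss if verdicts[g])
    background_ids = [
        g
        for g in verdicts
        if g not in truth.planted_specific and g not in truth.planted_near_miss
    ]
    if background_ids:
        fp_rate = sum(1 for g in background_ids if verdicts[g]) / len(
            background_ids
        )
    else:
        fp_rate = math.nan
    return RecoveryMetrics(
        sensitivity=sensitivity,
        near_miss_hits=near_hits,
        background_false_positive_rate=fp_rate,
    )


#: Product names cycled over planted-specific genes in companion annotations.
_PLANTED_PRODUCTS = (
    "Collagen-like protein 7",
    "Hypothetical protein {gene}",
    "Putative tyrosinase-like protein tyr 1",
    "IgGFc-binding protein (zonadhesin-like)",
    "Perlucin-like protein",
    "Serine protease inhibitor dipetalogastin-like",
)

_FULL_CLASS_NAMES = {
    "Ext": "Extracellular",
    "Cyt": "Cytoplasm",
    "Lys": "Lysosome/Vacuole",
    "Mit": "Mitochondrion",
    "Pla": "Plastid",
    "Mem": "Cell membrane",
    "ER": "Endoplasmic reticulum",
    "Nuc": "Nucleus",
}


def _collagen_like_sequence(rng: np.random.Generator, n_triplets: int) -> str:
    """Gly-X-Y repeats: glycine fraction exactly 1/3 >= 0.25 by construction."""
    xs = rng.choice(list("PAST"), n_triplets)
    ys = rng.choice(list(STANDARD_RESIDUES), n_triplets)
    return "".join(f"G{x}{y}" for x, y in zip(xs, ys))


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(STANDARD_RESIDUES), length))


def generate_companion_files(
    truth: SyntheticTruth, out_dir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Write protein FASTA, gene-protein map, domain scan and localization TSVs.

    Protein IDs are derived from gene IDs (``SYP_`` prefix) so the files are
    mutually consistent.  Planted-specific genes cycle through realistic
    product names; those named collagen-like get collagen-like sequences
    (glycine >= 25% by construction) and a triple-helix domain-scan row, and
    planted localizations are biased extracellular.  Near-miss genes get
    uniform-random sequences.  All files parse through the annotation-table
    parsers.
    """
    rng = np.random.default_rng(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    specific = sorted(truth.planted_specific)
    near_miss = sorted(truth.planted_near_miss)

    def protein_id(gene_id: str) -> str:
        return "SYP_" + gene_id.split("_", 1)[1]

    fasta_path = out_dir / "proteins.faa"
    map_path = out_dir / "protein_map.tsv"
    scan_path = out_dir / "domain_scan.tsv"
    loc_path = out_dir / "localizations.tsv"

    map_rows = []
    scan_rows = []
    loc_rows = []
    with fasta_path.open("w", encoding="utf-8") as fasta:
        for i, gene_id in enumerate(specific):
            pid = protein_id(gene_id)
            product = _PLANTED_PRODUCTS[i % len(_PLANTED_PRODUCTS)].format(
                gene=gene_id
            )
            map_rows.append((gene_id, pid, product))
            if product.startswith("Collagen"):
                seq = _collagen_like_sequence(rng, int(rng.integers(60, 120)))
                scan_rows.append(
                    (pid, "Collagen triple helix repeat", 10, 10 + len(seq) // 2)
                )
            else:
                seq = _random_sequence(rng, int(rng.integers(120, 400)))
                if rng.uniform() < 0.6:
                    start = int(rng.integers(1, max(2, len(seq) // 2)))
                    end = start + int(rng.integers(20, 60))
                    scan_rows.append((pid, "EGF-like domain", start, min(end, len(seq))))
            fasta.write(f">{pid} synthetic {product}\n{seq}\n")
            compartment = "Ext" if rng.uniform() < 0.8 else "Mem"
            loc_rows.append(
                (pid, _FULL_CLASS_NAMES[compartment], round(float(rng.uniform(0.4, 1.0)), 2))
            )
        for gene_id in near_miss:
            pid = protein_id(gene_id)
            map_rows.append((gene_id, pid, f"Hypothetical protein {gene_id}"))
            fasta.write(
                f">{pid} synthetic background-like\n"
                f"{_random_sequence(rng, int(rng.integers(100, 300)))}\n"
            )
            compartment = str(rng.choice(COMPARTMENTS))
            loc_rows.append(
                (pid, _FULL_CLASS_NAMES[compartment], round(float(rng.uniform(0.2, 1.0)), 2))
            )

    pd.DataFrame(
        map_rows, columns=["gene_id", "protein_id", "product_name"]
    ).to_csv(map_path, sep="\t", index=False)
    with scan_path.open("w", encoding="utf-8") as fh:
        fh.write("protein_id\tdomain_name\tstart\tend\n")
        for pid, name, start, end in scan_rows:
            fh.write(f"{pid}\t{name}\t{start}\t{end}\n")
    pd.DataFrame(
        loc_rows, columns=["ID", "Location", "score"]
    ).to_csv(loc_path, sep="\t", index=False)

    return {
        "fasta": fasta_path,
        "protein_map": map_path,
        "domain_scan": scan_path,
        "localization": loc_path,
    }
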