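"""RPKM expression matrices and sample-group schemes.

The screen operates on a dense genes x samples matrix of RPKM values (reads
per kilobase of transcript per million mapped reads) together with a scheme
that assigns each sample to a named group with one of three roles:

* ``reference`` — the stage whose specific genes are sought (e.g. the two
  pediveliger samples P1, P2);
* ``relaxed`` — samples allowed up to a higher fraction of the reference
  level (e.g. the immediately preceding late-umbo samples LU1, LU2, where
  pre-settlement transcription may already have begun);
* ``strict`` — all remaining stages and adult organs, held to the low bound.

Thresholds default to 0.20 (strict) and 0.70 (relaxed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

ROLES = ("reference", "relaxed", "strict")

DEFAULT_STRICT_THRESHOLD = 0.20
DEFAULT_RELAXED_THRESHOLD = 0.70

#: Statistics accepted for collapsing the reference samples to a single
#: per-gene level R.  "that of P1 or P2" is read as the max by default: a
#: non-reference sample must be low relative to the larger reference value.
REFERENCE_STATS = ("max", "min", "mean")


class ExpressionIOError(ValueError):
    """Raised for malformed matrix files or invalid expression values."""


class SchemeError(ValueError):
    """Raised for invalid or inconsistent group schemes."""


class ExpressionMatrix:
    """Dense, validated non-negative expression matrix (genes x samples).

    Thin wrapper over a ``pandas.DataFrame`` with gene IDs as the index and
    sample IDs as columns.  Construction validates the invariants the screen
    relies on: unique IDs, no missing cells, all values finite and >= 0.
    """

    def __init__(self, values: pd.DataFrame):
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate gene IDs: {dups[:5]}")
        if values.columns.has_duplicates:
            dups = values.columns[values.columns.duplicated()].unique().tolist()
            raise ExpressionIOError(f"duplicate sample IDs: {dups[:5]}")
        arr = values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise ExpressionIOError("matrix contains non-numeric cells")
        if np.isnan(arr).any():
            gi, si = np.argwhere(np.isnan(arr))[0]
            raise ExpressionIOError(
                f"missing value at gene {values.index[gi]!r}, "
                f"sample {values.columns[si]!r} (use fill_missing_zero to "
                "convert blanks/NA to 0.0)"
            )
        if arr.size and not np.isfinite(arr).all():
            raise ExpressionIOError("matrix contains non-finite values")
        if arr.size and (arr < 0).any():
            gi, si = np.argwhere(arr < 0)[0]
            raise ExpressionIOError(
                f"negative RPKM at gene {values.index[gi]!r}, "
                f"sample {values.columns[si]!r}"
            )
        self._values = values.astype(float)

    @classmethod
    def from_arrays(
        cls,
        gene_ids: Sequence[str],
        sample_ids: Sequence[str],
        values: np.ndarray | Sequence[Sequence[float]],
    ) -> "ExpressionMatrix":
        frame = pd.DataFrame(
            np.asarray(values, dtype=float),
            index=pd.Index(gene_ids, name="gene_id"),
            columns=list(sample_ids),
        )
        return cls(frame)

    @property
    def values(self) -> pd.DataFrame:
        return self._values

    @property
    def gene_ids(self) -> list[str]:
        return self._values.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self._values.columns.tolist()

    @property
    def n_genes(self) -> int:
        return self._values.shape[0]

    @property
    def n_samples(self) -> int:
        return self._values.shape[1]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"ExpressionMatrix({self.n_genes} genes x {self.n_samples} samples)"


@dataclass(frozen=True)
class SampleGroup:
    """A named set of samples sharing a screening role."""

    name: str
    samples: tuple[str, ...]
    role: str

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise SchemeError(
                f"group {self.name!r}: role must be one of {ROLES}, got {self.role!r}"
            )
        if not self.samples:
            raise SchemeError(f"group {self.name!r} has no samples")
        if len(set(self.samples)) != len(self.samples):
            raise SchemeError(f"group {self.name!r} lists a sample twice")


@dataclass(frozen=True)
class GroupScheme:
    """Sample-to-group assignment with per-role ratio thresholds.

    Invariants enforced at construction: at least one reference group, no
    sample in more than one group, thresholds in (0, 1], and
    ``strict_threshold <= relaxed_threshold`` (a screen where the strict
    bound is looser than the relaxed one is inconsistent).
    """

    groups: tuple[SampleGroup, ...]
    strict_threshold: float = DEFAULT_STRICT_THRESHOLD
    relaxed_threshold: float = DEFAULT_RELAXED_THRESHOLD
    reference_stat: str = "max"

    def __post_init__(self) -> None:
        if not any(g.role == "reference" for g in self.groups):
            raise SchemeError("scheme declares no reference group")
        seen: dict[str, str] = {}
        for g in self.groups:
            for s in g.samples:
                if s in seen:
                    raise SchemeError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {g.name!r}"
                    )
                seen[s] = g.name
        for label, value in (
            ("strict_threshold", self.strict_threshold),
            ("relaxed_threshold", self.relaxed_threshold),
        ):
            if not (0.0 < value <= 1.0):
                raise SchemeError(f"{label} must be in (0, 1], got {value}")
        if self.strict_threshold > self.relaxed_threshold:
            raise SchemeError(
                f"strict_threshold ({self.strict_threshold}) exceeds "
                f"relaxed_threshold ({self.relaxed_threshold})"
            )
        if self.reference_stat not in REFERENCE_STATS:
            raise SchemeError(
                f"reference_stat must be one of {REFERENCE_STATS}, "
                f"got {self.reference_stat!r}"
            )

    @property
    def reference_samples(self) -> tuple[str, ...]:
        return tuple(
            s for g in self.groups if g.role == "reference" for s in g.samples
        )

    @property
    def comparison_groups(self) -> tuple[SampleGroup, ...]:
        """Groups the screen tests against the reference level, in order."""
        return tuple(g for g in self.groups if g.role != "reference")

    def threshold_for(self, group: SampleGroup) -> float:
        if group.role == "strict":
            return self.strict_threshold
        if group.role == "relaxed":
            return self.relaxed_threshold
        raise SchemeError(f"group {group.name!r} has no threshold (role reference)")

    def all_samples(self) -> tuple[str, ...]:
        return tuple(s for g in self.groups for s in g.samples)

    def replace(self, **changes) -> "GroupScheme":
        from dataclasses import replace as _replace

        return _replace(self, **changes)


def load_rpkm_table(
    path: str | Path,
    *,
    fill_missing_zero: bool = False,
) -> ExpressionMatrix:
    """Read a tab-separated RPKM table into an :class:`ExpressionMatrix`.

    The file must be UTF-8 TSV with a header row of sample IDs and one gene
    per row, gene ID in the first column.  The first header cell may be
    empty or a label such as "Gene"; both are accepted.  Missing cells
    (blank or NA) are a hard error unless ``fill_missing_zero`` is set, in
    which case they become 0.0.
    """
    path = Path(path)
    try:
        frame = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            header=0,
            dtype=str,
            keep_default_na=False,
            encoding="utf-8",
        )
    except pd.errors.EmptyDataError as exc:
        raise ExpressionIOError(f"{path}: empty file") from exc
    frame.index = frame.index.astype(str)
    frame.index.name = "gene_id"

    raw = frame.to_numpy()
    numeric = np.empty(raw.shape, dtype=float)
    missing_tokens = {"", "NA", "NaN", "nan", "N/A"}
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = raw[i, j].strip()
            if cell in missing_tokens:
                if fill_missing_zero:
                    numeric[i, j] = 0.0
                    continue
                raise ExpressionIOError(
                    f"{path}: missing value at row {frame.index[i]!r}, "
                    f"column {frame.columns[j]!r} (pass fill_missing_zero "
                    "to treat as 0.0)"
                )
            try:
                numeric[i, j] = float(cell)
            except ValueError as exc:
                raise ExpressionIOError(
                    f"{path}: non-numeric cell {cell!r} at row "
                    f"{frame.index[i]!r}, column {frame.columns[j]!r}"
                ) from exc

    matrix = ExpressionMatrix(
        pd.DataFrame(numeric, index=frame.index, columns=frame.columns)
    )
    logger.info(
        "loaded %d genes x %d samples from %s",
        matrix.n_genes,
        matrix.n_samples,
        path,
    )
    return matrix


def write_rpkm_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix in the same TSV dialect ``load_rpkm_table`` reads.

    Values are formatted with :func:`repr`-style shortest round-trip floats,
    so a load/write cycle reproduces finite decimal inputs bit-exactly.
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("Gene\t" + "\t".join(matrix.sample_ids) + "\n")
        for gene_id, row in matrix.values.iterrows():
            cells = "\t".join(_format_float(v) for v in row.to_numpy())
            fh.write(f"{gene_id}\t{cells}\n")


def _format_float(value: float) -> str:
    # repr() gives the shortest string that round-trips the double exactly;
    # trim a trailing ".0" so integers print as integers.
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


def load_group_scheme(path: str | Path) -> GroupScheme:
    """Read a group scheme from a YAML config file.

    Expected layout::

        groups:
          pediveliger: {role: reference, samples: [P1, P2]}
          late_umbo:   {role: relaxed,   samples: [LU1, LU2]}
          other:       {role: strict,    samples: [E, T1, ...]}
        strict_threshold: 0.20    # optional, default 0.20
        relaxed_threshold: 0.70   # optional, default 0.70
        reference_stat: max       # optional, default max

    Unknown sample IDs are not checked here — the matrix is not available at
    load time; the screen reports them.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping) or "groups" not in raw:
        raise SchemeError(f"{path}: scheme file must define a 'groups' mapping")
    return scheme_from_mapping(raw)


def scheme_from_mapping(raw: Mapping) -> GroupScheme:
    """Build a :class:`GroupScheme` from a parsed config mapping."""
    groups = []
    for name, spec in raw["groups"].items():
        if not isinstance(spec, Mapping) or "role" not in spec or "samples" not in spec:
            raise SchemeError(
                f"group {name!r}: expected mapping with 'role' and 'samples'"
            )
        samples = spec["samples"]
        if isinstance(samples, str) or not isinstance(samples, Iterable):
            raise SchemeError(f"group {name!r}: 'samples' must be a list")
        groups.append(
            SampleGroup(
                name=str(name),
                samples=tuple(str(s) for s in samples),
                role=str(spec["role"]),
            )
        )
    kwargs = {}
    for key in ("strict_threshold", "relaxed_threshold"):
        if key in raw and raw[key] is not None:
            try:
                kwargs[key] = float(raw[key])
            except (TypeError, ValueError) as exc:
                raise SchemeError(f"{key} must be a number, got {raw[key]!r}") from exc
    if "reference_stat" in raw and raw["reference_stat"] is not None:
        kwargs["reference_stat"] = str(raw["reference_stat"])
    return GroupScheme(groups=tuple(groups), **kwargs)


def write_group_scheme(scheme: GroupScheme, path: str | Path) -> None:
    """Serialize a scheme to the YAML layout ``load_group_scheme`` reads."""
    doc = {
        "groups": {
            g.name: {"role": g.role, "samples": list(g.samples)}
            for g in scheme.groups
        },
        "strict_threshold": scheme.strict_threshold,
        "relaxed_threshold": scheme.relaxed_threshold,
        "reference_stat": scheme.reference_stat,
    }
    with Path(path).open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
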