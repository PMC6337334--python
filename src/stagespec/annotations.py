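"""Candidate-table construction and annotation summaries.

After the screen, candidates are joined to protein-level annotations into a
five-column table (gene ID, protein ID, product name, functional group,
subcellular localization).  This module loads and writes that table,
classifies products as hypothetical proteins, assigns functional groups from
editable keyword rules, tallies localization compartments, and parses the
tabular outputs of external domain scanners (InterProScan-style TSV) and
subcellular-localization predictors (DeepLoc-style TSV).  The external tools
are never run here — only their outputs are consumed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

#: Closed compartment vocabulary (DeepLoc 1.0 classes, abbreviated).
COMPARTMENTS = ("Ext", "Cyt", "Lys", "Mit", "Pla", "Mem", "ER", "Nuc")

#: Normalization of predictor class names and printed variants to the
#: vocabulary.  Includes the variants seen in published candidate tables
#: ("Plast" for plastid) and full DeepLoc class names.
_COMPARTMENT_ALIASES = {
    "ext": "Ext",
    "extracellular": "Ext",
    "cyt": "Cyt",
    "cytoplasm": "Cyt",
    "lys": "Lys",
    "lysosome": "Lys",
    "lysosome/vacuole": "Lys",
    "mit": "Mit",
    "mitochondrion": "Mit",
    "mitochondria": "Mit",
    "pla": "Pla",
    "plast": "Pla",
    "plastid": "Pla",
    "mem": "Mem",
    "membrane": "Mem",
    "cell membrane": "Mem",
    "plasma membrane": "Mem",
    "er": "ER",
    "endoplasmic reticulum": "ER",
    "nuc": "Nuc",
    "nucleus": "Nuc",
}

#: Controlled functional-group vocabulary from the candidate-table schema.
FUNCTIONAL_GROUPS = (
    "Hypothetical protein",
    "Enzyme",
    "Protease inhibitor",
    "Structural protein",
    "Calcification-related protein and calcium-binding protein",
    "Other",
)

#: Ordered keyword rules for functional-group assignment from a product
#: name.  First matching rule wins; names starting with "hypothetical
#: protein" are classified before the keyword pass.  Editable: pass your own
#: rules to assign_functional_group.
DEFAULT_GROUP_RULES: tuple[tuple[str, str], ...] = (
    ("inhibitor", "Protease inhibitor"),
    ("tyrosinase", "Enzyme"),
    ("peroxidase", "Enzyme"),
    ("anhydrase", "Enzyme"),
    ("hyaluronidase", "Enzyme"),
    ("hyaluronan", "Enzyme"),
    ("peptidase", "Enzyme"),
    ("proteinase", "Enzyme"),
    ("protease", "Enzyme"),
    ("collagen", "Structural protein"),
    ("tenascin", "Structural protein"),
    ("iggfc", "Structural protein"),
    ("hemicentin", "Structural protein"),
    ("egf", "Structural protein"),
    ("perlucin", "Calcification-related protein and calcium-binding protein"),
    ("calmodulin", "Calcification-related protein and calcium-binding protein"),
    ("cadherin", "Calcification-related protein and calcium-binding protein"),
    ("aggrecan", "Calcification-related protein and calcium-binding protein"),
    ("receptor", "Calcification-related protein and calcium-binding protein"),
)

CANDIDATE_COLUMNS = (
    "gene_id",
    "protein_id",
    "product_name",
    "functional_group",
    "localization",
)


class AnnotationError(ValueError):
    """Raised for malformed annotation tables or scanner outputs."""


@dataclass(frozen=True)
class LocalizationPrediction:
    """A predicted compartment with its classifier confidence in [0, 1]."""

    compartment: str
    score: float

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise AnnotationError(
                f"unknown compartment {self.compartment!r}; "
                f"expected one of {COMPARTMENTS}"
            )
        if not (0.0 <= self.score <= 1.0):
            raise AnnotationError(
                f"localization score {self.score} outside [0, 1]"
            )

    def __str__(self) -> str:
        return f"{self.compartment} {_trim_score(self.score)}"


@dataclass(frozen=True)
class CandidateRecord:
    """One candidate-table row."""

    gene_id: str
    protein_id: str
    product_name: str
    functional_group: str
    localization: LocalizationPrediction | None = None


@dataclass(frozen=True)
class DomainHit:
    """A conserved-domain match, 1-based inclusive residue coordinates."""

    protein_id: str
    domain_name: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1 or self.start > self.end:
            raise AnnotationError(
                f"{self.protein_id}: invalid domain coordinates "
                f"{self.start}-{self.end} (need 1 <= start <= end)"
            )


def normalize_compartment(label: str) -> str:
    """Map a predictor class name or printed variant to the vocabulary."""
    key = label.strip().lower()
    if key not in _COMPARTMENT_ALIASES:
        raise AnnotationError(
            f"unknown compartment label {label!r}; "
            f"known labels normalize to {COMPARTMENTS}"
        )
    return _COMPARTMENT_ALIASES[key]


def parse_localization_cell(cell: str) -> LocalizationPrediction | None:
    """Parse a table cell of the form ``"<compartment> <score>"``."""
    cell = cell.strip()
    if not cell:
        return None
    parts = cell.rsplit(None, 1)
    if len(parts) != 2:
        raise AnnotationError(
            f"localization cell {cell!r} is not '<compartment> <score>'"
        )
    compartment = normalize_compartment(parts[0])
    try:
        score = float(parts[1])
    except ValueError as exc:
        raise AnnotationError(
            f"localization score {parts[1]!r} is not a number"
        ) from exc
    return LocalizationPrediction(compartment=compartment, score=score)


def _trim_score(score: float) -> str:
    text = f"{score:g}"
    return text


def classify_hypothetical(product_name: str) -> bool:
    """True iff the product name begins with "hypothetical protein".

    Case-insensitive, leading whitespace ignored.  Hypothetical proteins are
    predicted products with no functional annotation in reference databases.
    """
    return product_name.strip().lower().startswith("hypothetical protein")


def assign_functional_group(
    product_name: str,
    rules: Sequence[tuple[str, str]] = DEFAULT_GROUP_RULES,
) -> str:
    """Assign a functional group from ordered keyword rules.

    Hypothetical proteins are recognized first; otherwise the first rule
    whose keyword occurs (case-insensitively) in the product name wins, and
    names matching no rule fall through to "Other".
    """
    if classify_hypothetical(product_name):
        return "Hypothetical protein"
    lowered = product_name.lower()
    for keyword, group in rules:
        if keyword.lower() in lowered:
            return group
    return "Other"


def load_candidate_table(path: str | Path) -> list[CandidateRecord]:
    """Read a five-column candidate TSV into validated records.

    Columns: gene_id, protein_id, product_name, functional_group,
    localization (``"<compartment> <score>"``, possibly empty).  Compartment
    labels are normalized to the closed vocabulary; unknown labels and
    scores outside [0, 1] are errors.  Duplicate gene IDs are rejected.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    missing = [c for c in CANDIDATE_COLUMNS if c not in frame.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    records: list[CandidateRecord] = []
    seen: set[str] = set()
    for _, row in frame.iterrows():
        gene_id = row["gene_id"].strip()
        if gene_id in seen:
            raise AnnotationError(f"{path}: duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        records.append(
            CandidateRecord(
                gene_id=gene_id,
                protein_id=row["protein_id"].strip(),
                product_name=row["product_name"].strip(),
                functional_group=row["functional_group"].strip(),
                localization=parse_localization_cell(row["localization"]),
            )
        )
    return records


def write_candidate_table(
    records: Iterable[CandidateRecord], path: str | Path
) -> None:
    """Write records in the TSV dialect ``load_candidate_table`` reads."""
    rows = []
    for r in records:
        rows.append(
            {
                "gene_id": r.gene_id,
                "protein_id": r.protein_id,
                "product_name": r.product_name,
                "functional_group": r.functional_group,
                "localization": str(r.localization) if r.localization else "",
            }
        )
    pd.DataFrame(rows, columns=list(CANDIDATE_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def tally_localizations(
    records: Iterable[CandidateRecord],
    subset: Callable[[CandidateRecord], bool] | None = None,
) -> dict[str, int]:
    """Count records per predicted compartment.

    Records without a localization prediction are counted under ``"none"``.
    ``subset`` optionally filters records first (e.g. hypothetical proteins
    only).  The tally over all compartments plus "none" always sums to the
    number of (filtered) records.
    """
    counts: dict[str, int] = {}
    for record in records:
        if subset is not None and not subset(record):
            continue
        key = record.localization.compartment if record.localization else "none"
        counts[key] = counts.get(key, 0) + 1
    return counts


def parse_domain_scan(path: str | Path) -> list[DomainHit]:
    """Parse conserved-domain hits from a signature-scanner TSV.

    Accepts the standard InterProScan tab-separated layout (no header;
    protein accession in column 1, signature description in column 6, start
    and stop in columns 7-8 of 11+) and a minimal four-column layout
    (protein, domain name, start, end) with or without a header line.
    Coordinates are 1-based inclusive and preserved verbatim.
    """
    path = Path(path)
    hits: list[DomainHit] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 8:
                protein, name, start_s, end_s = (
                    fields[0],
                    fields[5] or fields[4],
                    fields[6],
                    fields[7],
                )
            elif len(fields) == 4:
                protein, name, start_s, end_s = fields
            else:
                raise AnnotationError(
                    f"{path}:{lineno}: expected 4 or >=8 tab-separated "
                    f"columns, got {len(fields)}"
                )
            if lineno == 1 and not _is_int(start_s) and not _is_int(end_s):
                continue  # header line in the minimal layout
            if not _is_int(start_s) or not _is_int(end_s):
                raise AnnotationError(
                    f"{path}:{lineno}: non-integer domain coordinates "
                    f"{start_s!r}-{end_s!r}"
                )
            hits.append(
                DomainHit(
                    protein_id=protein.strip(),
                    domain_name=name.strip(),
                    start=int(start_s),
                    end=int(end_s),
                )
            )
    return hits


def _is_int(text: str) -> bool:
    return bool(re.fullmatch(r"[+-]?\d+", text.strip()))


def domain_architecture_summary(
    hits: Iterable[DomainHit],
    candidate_protein_ids: Sequence[str],
) -> tuple[dict[str, int], int]:
    """Per-protein domain counts over a candidate set.

    Returns ``(counts, n_with_domain)`` where ``counts`` maps every
    candidate protein ID to its number of domain hits (zero-hit proteins
    included) and ``n_with_domain`` is the headline count of candidates with
    at least one predicted domain or repeat.  Hits for proteins outside the
    candidate list are ignored.
    """
    counts = {pid: 0 for pid in candidate_protein_ids}
    for hit in hits:
        if hit.protein_id in counts:
            counts[hit.protein_id] += 1
    n_with_domain = sum(1 for n in counts.values() if n > 0)
    return counts, n_with_domain


def parse_localization_output(
    path: str | Path,
) -> dict[str, LocalizationPrediction]:
    """Parse a subcellular-localization predictor's tabular output.

    Expects a header TSV whose first column is the protein ID and second
    column the predicted class name (full names such as "Extracellular" or
    "Endoplasmic reticulum" are normalized to the compartment vocabulary).
    The retained score is taken from the per-class score column matching the
    predicted class when such columns are present, otherwise from a column
    named "score", otherwise from the third column.  Duplicate protein IDs
    are an error.
    """
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    if frame.shape[1] < 2:
        raise AnnotationError(f"{path}: need at least ID and class columns")
    id_col, class_col = frame.columns[0], frame.columns[1]

    # Per-class score columns, if the header carries class names.
    class_columns: dict[str, str] = {}
    for col in frame.columns[2:]:
        key = col.strip().lower()
        if key in _COMPARTMENT_ALIASES:
            class_columns[_COMPARTMENT_ALIASES[key]] = col
    score_col = next(
        (c for c in frame.columns[2:] if c.strip().lower() == "score"), None
    )

    predictions: dict[str, LocalizationPrediction] = {}
    for _, row in frame.iterrows():
        protein_id = row[id_col].strip()
        if protein_id in predictions:
            raise AnnotationError(f"{path}: duplicate protein ID {protein_id!r}")
        compartment = normalize_compartment(row[class_col])
        if compartment in class_columns:
            raw_score = row[class_columns[compartment]]
        elif score_col is not None:
            raw_score = row[score_col]
        elif frame.shape[1] >= 3:
            raw_score = row[frame.columns[2]]
        else:
            raise AnnotationError(
                f"{path}: no score column found for {protein_id!r}"
            )
        try:
            score = float(raw_score)
        except ValueError as exc:
            raise AnnotationError(
                f"{path}: non-numeric score {raw_score!r} for {protein_id!r}"
            ) from exc
        predictions[protein_id] = LocalizationPrediction(
            compartment=compartment, score=score
        )
    return predictions


def load_protein_map(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a gene-to-protein map TSV (gene_id, protein_id, product_name)."""
    path = Path(path)
    frame = pd.read_csv(
        path, sep="\t", dtype=str, keep_default_na=False, encoding="utf-8"
    )
    needed = ["gene_id", "protein_id", "product_name"]
    missing = [c for c in needed if c not in frame.columns]
    if missing:
        raise AnnotationError(f"{path}: missing columns {missing}")
    mapping: dict[str, tuple[str, str]] = {}
    for _, row in frame.iterrows():
        gene_id = row["gene_id"].strip()
        if gene_id in mapping:
            raise AnnotationError(f"{path}: duplicate gene ID {gene_id!r}")
        mapping[gene_id] = (row["protein_id"].strip(), row["product_name"].strip())
    return mapping


def build_candidate_records(
    selected_gene_ids: Sequence[str],
    protein_map: Mapping[str, tuple[str, str]],
    localizations: Mapping[str, LocalizationPrediction] | None = None,
    rules: Sequence[tuple[str, str]] = DEFAULT_GROUP_RULES,
) -> list[CandidateRecord]:
    """Assemble candidate records for screen hits.

    ``protein_map`` maps gene ID to ``(protein_id, product_name)``; genes
    without an entry get an empty protein ID and a "hypothetical protein
    <gene>" placeholder name.  Functional groups are assigned by keyword
    rules; localizations, keyed by protein ID, are attached when available.
    """
    records = []
    for gene_id in selected_gene_ids:
        protein_id, product_name = protein_map.get(
            gene_id, ("", f"Hypothetical protein {gene_id}")
        )
        localization = (
            localizations.get(protein_id) if localizations else None
        )
        records.append(
            CandidateRecord(
                gene_id=gene_id,
                protein_id=protein_id,
                product_name=product_name,
                functional_group=assign_functional_group(product_name, rules),
                localization=localization,
            )
        )
    return records
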