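"""Packaged reference datasets."""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from stagespec.annotations import CandidateRecord, load_candidate_table


def pediveliger_candidates_path() -> Path:
    """Path to the packaged pediveliger candidate table.

    The 59 genes selected as specifically expressed at the pediveliger stage
    of *Crassostrea gigas*, with protein IDs, product names, functional
    groups and DeepLoc 1.0 localization predictions, transcribed from the
    published candidate table.
    """
    return Path(
        resources.files("stagespec").joinpath("data/pediveliger_candidates.tsv")
    )


def pediveliger_candidates() -> list[CandidateRecord]:
    """Load the packaged pediveliger candidate table (59 records)."""
    return load_candidate_table(pediveliger_candidates_path())
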