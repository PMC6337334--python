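"""Human-readable summaries, run manifests and the end-to-end pipeline.

The pipeline ties the stages together in the order the screening study runs
them: screen the RPKM matrix, join hits to protein annotations into the
candidate table, profile compositions, and emit a plain-text report with the
headline counts (candidates selected, localization tally, hypothetical
count, domain-bearing count).  Every output directory gets a JSON manifest
recording inputs, parameters and package version, so a run can be repeated
byte-identically.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from stagespec.annotations import (
    CandidateRecord,
    DomainHit,
    classify_hypothetical,
    build_candidate_records,
    domain_architecture_summary,
    load_protein_map,
    parse_domain_scan,
    parse_localization_output,
    tally_localizations,
    write_candidate_table,
)
from stagespec.composition import batch_composition, write_composition_table
from stagespec.expression import load_group_scheme, load_rpkm_table
from stagespec.screen import (
    ScreenSummary,
    screen,
    summarize,
    write_screen_results,
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""


@dataclass
class RunManifest:
    """Record of one run: subcommand, inputs, parameters, version, time."""

    subcommand: str
    inputs: dict[str, str] = field(default_factory=dict)
    parameters: dict[str, object] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def __post_init__(self) -> None:
        if not self.version:
            from stagespec import __version__

            self.version = __version__
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()

    def write(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(self.__dict__, fh, indent=2, sort_keys=True)
            fh.write("\n")


def _pct(numerator: int, denominator: int) -> str:
    if denominator == 0:
        return "n/a"
    return f"{100.0 * numerator / denominator:.1f}%"


def candidate_report(
    records: Sequence[CandidateRecord],
    domain_hits: Iterable[DomainHit] | None = None,
    screen_summary: ScreenSummary | None = None,
) -> str:
    """Plain-text summary of a candidate table.

    States the candidate count, the per-compartment localization tally, the
    hypothetical-protein count and percentage (with its extracellular
    subset), the functional-group breakdown, and — when scanner output is
    supplied — the number of candidates with at least one predicted domain.
    """
    lines: list[str] = []
    if screen_summary is not None:
        fraction = screen_summary.fraction_selected
        fraction_text = (
            "n/a" if math.isnan(fraction) else f"{100.0 * fraction:.2f}%"
        )
        lines.append(
            f"Screen: {screen_summary.n_selected} of "
            f"{screen_summary.n_genes_total} genes selected ({fraction_text}) "
            f"at thresholds strict<{screen_summary.strict_threshold:g}, "
            f"relaxed<{screen_summary.relaxed_threshold:g} "
            f"(reference stat: {screen_summary.reference_stat})"
        )
    n = len(records)
    lines.append(f"Candidates: {n}")

    tally = tally_localizations(records)
    tally_text = ", ".join(
        f"{compartment}: {count}"
        for compartment, count in sorted(
            tally.items(), key=lambda kv: (-kv[1], kv[0])
        )
    )
    lines.append(f"Localization tally: {tally_text if tally_text else 'none'}")
    lines.append(f"Extracellular: {tally.get('Ext', 0)}")

    hypothetical = [r for r in records if classify_hypothetical(r.product_name)]
    lines.append(
        f"Hypothetical proteins: {len(hypothetical)} ({_pct(len(hypothetical), n)})"
    )
    hyp_ext = tally_localizations(
        records, subset=lambda r: classify_hypothetical(r.product_name)
    ).get("Ext", 0)
    lines.append(f"Extracellular hypothetical proteins: {hyp_ext}")

    groups: dict[str, int] = {}
    for r in records:
        groups[r.functional_group] = groups.get(r.functional_group, 0) + 1
    for group_name, count in sorted(groups.items(), key=lambda kv: (-kv[1], kv[0])):
        lines.append(f"  {group_name}: {count}")

    if domain_hits is not None:
        _, n_with_domain = domain_architecture_summary(
            domain_hits, [r.protein_id for r in records if r.protein_id]
        )
        lines.append(f"Candidates with >=1 predicted domain: {n_with_domain}")
    return "\n".join(lines) + "\n"


def run_pipeline(config: Mapping[str, object], out_dir: str | Path) -> Path:
    """Run screen -> annotate -> compose -> report from a config mapping.

    Required config keys: ``matrix`` and ``scheme`` (paths).  Optional:
    ``proteins`` (gene-protein map TSV), ``localizations`` (predictor TSV),
    ``domains`` (scanner TSV), ``fasta`` (protein FASTA for composition).
    Writes screen results, candidate table, composition table (when a FASTA
    is given), a plain-text report and a run manifest into ``out_dir``; any
    stage failure aborts with the stage name and cause.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc

    if "matrix" not in config or "scheme" not in config:
        raise PipelineError(
            "stage 'screen' failed: config must name 'matrix' and 'scheme'"
        )

    matrix = stage("screen", load_rpkm_table, str(config["matrix"]))
    scheme = stage("screen", load_group_scheme, str(config["scheme"]))
    results = stage("screen", screen, matrix, scheme)
    write_screen_results(results, out_dir / "screen_results.tsv")
    summary = summarize(results)

    protein_map = (
        stage("annotate", load_protein_map, str(config["proteins"]))
        if config.get("proteins")
        else {}
    )
    localizations = (
        stage(
            "annotate", parse_localization_output, str(config["localizations"])
        )
        if config.get("localizations")
        else None
    )
    records = stage(
        "annotate",
        build_candidate_records,
        results.selected_ids(),
        protein_map,
        localizations,
    )
    write_candidate_table(records, out_dir / "candidates.tsv")

    domain_hits = (
        stage("annotate", parse_domain_scan, str(config["domains"]))
        if config.get("domains")
        else None
    )

    if config.get("fasta"):
        profiles = stage("compose", batch_composition, str(config["fasta"]))
        candidate_proteins = {r.protein_id for r in records}
        profiles = [p for p in profiles if p.protein_id in candidate_proteins]
        write_composition_table(profiles, out_dir / "composition.tsv")

    report = candidate_report(records, domain_hits, summary)
    (out_dir / "report.txt").write_text(report, encoding="utf-8")

    manifest = RunManifest(
        subcommand="pipeline",
        inputs={k: str(v) for k, v in config.items() if v},
        parameters={
            "strict_threshold": scheme.strict_threshold,
            "relaxed_threshold": scheme.relaxed_threshold,
            "reference_stat": scheme.reference_stat,
        },
    )
    manifest.write(out_dir / "manifest.json")
    return out_dir
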