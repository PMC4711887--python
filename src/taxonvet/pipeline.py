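"""End-to-end orchestration of the assessment workflow.

Stages run in a fixed order — assemble/assess, link, summarize, model — each
consuming and producing the documented delimited formats so they are also
independently scriptable.  Every run writes a provenance manifest (input
hashes, config snapshot, tool version, output listing); a stage failure stops
the run with earlier outputs intact.
"""

from __future__ import annotations

import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field, asdict
from pathlib import Path

from . import __version__
from .authority import Authority
from .driver_models import DEFAULT_COVARIATES, ModelSpec, fit_issue_model
from .dwc_io import (
    read_name_table,
    read_occurrence_table,
    write_assessment_table,
)
from .issue_detection import DetectionConfig, assess_table
from .occurrence_link import link_occurrences, standardize_table
from .summary_stats import issue_overlap, project_effort, summarize_issues

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger("taxonvet")


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage, with record context when known."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunConfig:
    """Inputs, thresholds and output location of one pipeline run."""

    names_path: Path
    authority_path: Path
    output_dir: Path
    occurrences_path: Path | None = None
    region_map_path: Path | None = None
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    #: fit the issue-driver model for these responses (needs occurrences)
    model_responses: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        for label, p in (
            ("names", self.names_path),
            ("authority", self.authority_path),
            ("occurrences", self.occurrences_path),
            ("region map", self.region_map_path),
        ):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run assemble → assess → link → summarize; returns the manifest dict.

    Outputs written to ``config.output_dir``: ``assessments.tsv``,
    ``summary.tsv``, ``overlap.tsv``, optional ``model_*.tsv`` coefficient
    tables, and ``manifest.json``.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "taxonvet",
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "inputs": {},
        "outputs": [],
        "stages": [],
    }
    for label, p in (
        ("names", config.names_path),
        ("authority", config.authority_path),
        ("occurrences", config.occurrences_path),
    ):
        if p is not None:
            manifest["inputs"][label] = {"path": str(p), "sha256": _sha256(Path(p))}

    # stage: assess
    try:
        names = read_name_table(config.names_path)
        authority = Authority.from_file(config.authority_path)
        assessments = assess_table(names, authority, config.detection)
        assessed_path = out / "assessments.tsv"
        write_assessment_table(assessed_path, assessments)
        manifest["outputs"].append(str(assessed_path))
        manifest["stages"].append({"stage": "assess", "n_records": len(assessments)})
        logger.info("assess: %d name combinations assessed", len(assessments))
    except Exception as exc:
        raise PipelineError("assess", str(exc)) from exc

    # stage: link
    link = None
    if config.occurrences_path is not None:
        try:
            occurrences = read_occurrence_table(config.occurrences_path)
            link = link_occurrences(names, occurrences)
            manifest["stages"].append(
                {
                    "stage": "link",
                    "n_occurrences": len(occurrences),
                    "n_matched": len(link.matched),
                    "n_unmatched_names": len(link.unmatched_name_ids),
                    "n_unmatched_occurrences": len(link.unmatched_occurrence_ids),
                }
            )
            logger.info("link: %d of %d occurrences matched",
                        len(link.matched), len(occurrences))
        except Exception as exc:
            raise PipelineError("link", str(exc)) from exc

    # stage: summarize
    try:
        summary = summarize_issues(assessments, link)
        summary_path = out / "summary.tsv"
        with open(summary_path, "w", encoding="utf-8") as fh:
            for row in summary.to_rows():
                fh.write("\t".join(row) + "\n")
        overlap = issue_overlap(assessments)
        overlap_path = out / "overlap.tsv"
        with open(overlap_path, "w", encoding="utf-8") as fh:
            fh.write("issues\tcount\n")
            for key in sorted(overlap, key=lambda k: (len(k), sorted(k))):
                fh.write("+".join(sorted(key)) + "\t" + str(overlap[key]) + "\n")
        manifest["outputs"] += [str(summary_path), str(overlap_path)]
        manifest["stages"].append(
            {
                "stage": "summarize",
                "n_with_issue": summary["Has issue"].names,
                "n_with_error": summary["Has error"].names,
                "projected_person_hours": project_effort(len(assessments)),
            }
        )
    except Exception as exc:
        raise PipelineError("summarize", str(exc)) from exc

    # stage: model (optional)
    if config.model_responses and link is not None:
        try:
            import pandas as pd

            kept, excluded = standardize_table(
                [occ for _, occ in link.matched]
            )
            cov_by_occ = dict(kept)
            by_id = {a.id: a for a in assessments}
            rows = []
            for name_id, occ in link.matched:
                vec = cov_by_occ.get(occ.occurrence_id)
                a = by_id.get(name_id)
                if vec is None or a is None:
                    continue
                rows.append(
                    {
                        "basisOfRecord": vec.basisOfRecord,
                        "region": vec.region,
                        "clade": vec.clade,
                        "year": vec.year,
                        "institutionRecords": vec.institutionRecords,
                        "hasIssue": int(a.hasIssue),
                        "hasMisspelling": int(a.hasMisspelling),
                        "hasFormatError": int(a.hasFormatError),
                        "hasConceptualError": int(a.hasConceptualError),
                        "isSynonym": a.isSynonym,
                    }
                )
            frame = pd.DataFrame(rows)
            for response in config.model_responses:
                spec = ModelSpec(response=response,
                                 main_effects=DEFAULT_COVARIATES)
                res = fit_issue_model(frame, spec)
                coef_path = out / f"model_{response}.tsv"
                res.coefficient_table().to_csv(coef_path, sep="\t")
                manifest["outputs"].append(str(coef_path))
                manifest["stages"].append(
                    {
                        "stage": "model",
                        "response": response,
                        "aic": res.aic,
                        "mcfadden_r2": res.mcfadden_r2,
                        "nagelkerke_r2": res.nagelkerke_r2,
                        "n": res.nobs,
                        "n_excluded": len(excluded),
                    }
                )
        except Exception as exc:
            raise PipelineError("model", str(exc)) from exc

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                             encoding="utf-8")
    return manifest
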