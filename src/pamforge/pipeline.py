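"""End-to-end orchestration: cluster -> match -> predict, with a manifest.

Every stage writes its artifact to the output directory; the manifest
records input hashes, parameters and per-stage record counts so a run can
be audited and reruns verified byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io
from .cluster import filter_cas9_min_length, greedy_cluster, write_cluster_table
from .match import MatchParams, dedupe_spacers, match_all, matched_segment, orient_spacers
from .model import CasLocus, GenomeRecord, PamPrediction
from .predict import CallParams, predict_cluster_pam

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    loci_path: str
    genomes_path: str
    out_dir: str
    identity_level: float = 0.98
    min_cas9_len: int = 950
    match_params: MatchParams = field(default_factory=MatchParams)
    call_params: CallParams = field(default_factory=CallParams)

    def validate(self) -> None:
        for p in (self.loci_path, self.genomes_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full prediction pipeline; returns the run manifest."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "inputs": {
            "loci": _sha256(config.loci_path),
            "genomes": _sha256(config.genomes_path),
        },
        "parameters": {
            "identity_level": config.identity_level,
            "min_cas9_len": config.min_cas9_len,
            "max_variations": config.match_params.max_variations,
            "flank_len": config.match_params.flank_len,
            "min_spacers": config.call_params.min_spacers,
        },
        "stages": {},
    }
    try:
        loci = io.read_locus_table(config.loci_path)
        genomes = io.read_fasta(config.genomes_path)
        manifest["stages"]["load"] = {"loci": len(loci), "genomes": len(genomes)}

        kept = filter_cas9_min_length(loci, config.min_cas9_len)
        manifest["stages"]["length_filter"] = {"kept": len(kept), "excluded": len(loci) - len(kept)}

        proteins = {l.locus_id: l.cas9_protein for l in kept}
        subtypes = {l.locus_id: l.subtype for l in kept}
        clusters = greedy_cluster(proteins, config.identity_level, subtypes=subtypes)
        write_cluster_table(clusters, out / "clusters.tsv")
        manifest["stages"]["cluster"] = {"clusters": len(clusters)}

        locus_by_id = {l.locus_id: l for l in kept}
        genome_by_id = {g.id: g for g in genomes}
        predictions: list[PamPrediction] = []
        all_matches = []
        eligible = 0
        for cluster in clusters:
            spacers = []
            for member in cluster.member_ids:
                spacers.extend(orient_spacers(locus_by_id[member]))
            unique, _ = dedupe_spacers(spacers)
            matches = match_all(unique, genomes, config.match_params)
            all_matches.extend(matches)
            spacer_by_id = {s.spacer_id: s for s in unique}
            flanked: dict[str, list[str]] = {}
            for m in matches:
                seq = spacer_by_id[m.spacer_id].sequence
                seg = matched_segment(m, genome_by_id[m.genome_id])
                flanked.setdefault(seq, []).append(m.up_flank + seg + m.down_flank)
            pred, _ = predict_cluster_pam(
                cluster.cluster_id, flanked, config.call_params, config.match_params.flank_len
            )
            if pred.n_spacers >= config.call_params.min_spacers:
                eligible += 1
            predictions.append(pred)
        io.write_matches(all_matches, out / "matches.tsv")
        io.write_predictions(predictions, out / "predictions.json")
        by_status: dict[str, int] = {}
        for p in predictions:
            by_status[p.status] = by_status.get(p.status, 0) + 1
        manifest["stages"]["match"] = {"matches": len(all_matches)}
        manifest["stages"]["predict"] = {
            "clusters_eligible": eligible,
            "predictions_by_status": by_status,
        }
    except Exception as exc:
        failed = len(manifest["stages"])
        stage_names = ["load", "length_filter", "cluster", "match", "predict"]
        manifest["failed_stage"] = stage_names[min(failed, len(stage_names) - 1)]
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        raise
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return manifest


def summarize_predictions(
    predictions: list[PamPrediction],
    cluster_subtypes: dict[str, str],
    min_spacers: int = 10,
) -> pd.DataFrame:
    """Per-subtype (and overall) fraction of eligible clusters with a
    predicted PAM. Eligible = at least ``min_spacers`` mapped spacers.
    Subtypes with no eligible cluster are omitted."""
    rows = []
    eligible = [p for p in predictions if p.n_spacers >= min_spacers]
    subtypes = sorted({cluster_subtypes.get(p.cluster_id, "unknown") for p in eligible})
    for st in subtypes + ["(all)"]:
        subset = (
            eligible
            if st == "(all)"
            else [p for p in eligible if cluster_subtypes.get(p.cluster_id, "unknown") == st]
        )
        if not subset:
            logger.info("subtype %s omitted: no eligible clusters", st)
            continue
        n_pred = sum(1 for p in subset if p.status == "predicted")
        rows.append(
            {
                "subtype": st,
                "n_eligible": len(subset),
                "n_predicted": n_pred,
                "fraction": n_pred / len(subset),
            }
        )
    return pd.DataFrame(rows)
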