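"""End-to-end pipeline orchestration with a config file and a run manifest.

Stages run in dependency order: conserve -> filter -> scan -> frameworks
-> assay. Any subset is selectable; a rerun with an unchanged config and
unchanged inputs reuses cached stage outputs (content hashes recorded in
the manifest) without re-executing the stage. Re-running with an
identical config reproduces identical result files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
import time

import pandas as pd

from . import __version__
from .conservation import call_ecrs, ecrs_to_bed, label_ecrs, windowed_identity, write_ecr_tsv
from .frameworks import find_frameworks, write_frameworks_json, write_frameworks_tsv
from .intervals import GenomicInterval
from .io import read_alignment, read_bed, read_fasta, read_gene_model, write_bed
from .motif_scan import read_pfm, read_hits_tsv, scan_all, write_hits_tsv
from .noncoding_filter import is_noncoding
from .reporter_stats import classify_elements, read_assay_table, write_results_tsv

logger = logging.getLogger("ncecr.pipeline")

STAGES = ("conserve", "filter", "scan", "frameworks", "assay")


class ConfigError(ValueError):
    """Invalid pipeline configuration; the message lists offending keys."""


class DataError(ValueError):
    """A stage failed on its input data."""


@dataclasses.dataclass
class StageRecord:
    params: dict
    inputs: dict[str, str]
    outputs: dict[str, str]
    status: str
    started: str
    finished: str


@dataclasses.dataclass
class RunManifest:
    config_hash: str
    version: str
    outdir: str
    stages: dict[str, StageRecord]

    def to_dict(self) -> dict:
        return {
            "config_hash": self.config_hash,
            "version": self.version,
            "outdir": self.outdir,
            "stages": {k: dataclasses.asdict(v) for k, v in self.stages.items()},
        }

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")


# ---------------------------------------------------------------------------
# Config loading / validation
# ---------------------------------------------------------------------------

_KNOWN_KEYS = {
    "pipeline": {"outdir", "stages"},
    "conserve": {"alignment", "dialect", "gene_model", "window", "min_len", "min_identity"},
    "filter": {"annotations", "max_orf_aa"},
    "scan": {"pfm", "fasta", "min_matrix_sim", "min_core_sim"},
    "frameworks": {"tolerances", "min_tfs", "hits"},
    "assay": {"table", "alpha", "control", "welch", "fdr"},
}


def load_config(path: str | os.PathLike) -> dict:
    path = os.fspath(path)
    if path.endswith(".toml"):
        import tomllib

        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    else:
        import yaml

        with open(path) as fh:
            cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    validate_config(cfg)
    return cfg


def validate_config(cfg: dict) -> None:
    """Schema and bounds check; raises ConfigError listing offending keys."""
    errors: list[str] = []
    for section, body in cfg.items():
        if section not in _KNOWN_KEYS:
            errors.append(f"unknown section {section!r}")
            continue
        if body is None:
            continue
        if not isinstance(body, dict):
            errors.append(f"section {section!r} must be a mapping")
            continue
        unknown = set(body) - _KNOWN_KEYS[section]
        errors.extend(f"unknown key {section}.{k}" for k in sorted(unknown))

    def check(section, key, pred, what):
        body = cfg.get(section) or {}
        if isinstance(body, dict) and key in body and not pred(body[key]):
            errors.append(f"{section}.{key}: {what} (got {body[key]!r})")

    check("conserve", "min_identity", lambda v: 0 < v <= 1, "must be in (0, 1]")
    check("conserve", "min_len", lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1")
    check("conserve", "window", lambda v: isinstance(v, int) and v >= 1, "must be an integer >= 1")
    check("conserve", "dialect", lambda v: v in ("maf", "axt"), "must be 'maf' or 'axt'")
    check("filter", "max_orf_aa", lambda v: isinstance(v, int) and v >= 0, "must be an integer >= 0")
    check("scan", "min_matrix_sim", lambda v: 0 <= v <= 1, "must be in [0, 1]")
    check("scan", "min_core_sim", lambda v: 0 <= v <= 1, "must be in [0, 1]")
    check("frameworks", "min_tfs", lambda v: isinstance(v, int) and v >= 2, "must be an integer >= 2")
    check("frameworks", "tolerances", lambda v: isinstance(v, (list, tuple)) and all(
        isinstance(t, int) and t >= 0 for t in v), "must be a list of integers >= 0")
    check("assay", "alpha", lambda v: 0 < v < 1, "must be in (0, 1)")
    stages = (cfg.get("pipeline") or {}).get("stages") if isinstance(cfg.get("pipeline"), dict) else None
    if stages is not None:
        for s in stages:
            if s not in STAGES:
                errors.append(f"pipeline.stages: unknown stage {s!r}")
    if errors:
        raise ConfigError("invalid configuration: " + "; ".join(errors))


def _hash_file(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _hash_config(cfg: dict) -> str:
    return hashlib.sha256(json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()


def _now() -> str:
    return time.strftime("%Y-%m-%dT%H:%M:%S")


# ---------------------------------------------------------------------------
# Stages. Each has plan(cfg, outdir) -> (params, inputs, outputs) declaring
# parameters and file paths, and execute(cfg, outdir) doing the work.
# ---------------------------------------------------------------------------


def _plan_conserve(cfg: dict, outdir: str):
    body = cfg.get("conserve") or {}
    if "alignment" not in body:
        raise ConfigError("conserve.alignment is required for the conserve stage")
    params = {
        "window": body.get("window", body.get("min_len", 100)),
        "min_len": body.get("min_len", 100),
        "min_identity": body.get("min_identity", 0.75),
        "dialect": body.get("dialect", "maf"),
    }
    inputs = {"alignment": body["alignment"]}
    if body.get("gene_model"):
        inputs["gene_model"] = body["gene_model"]
    outputs = {"bed": os.path.join(outdir, "ecrs.bed"), "tsv": os.path.join(outdir, "ecrs.tsv")}
    return params, inputs, outputs


def _exec_conserve(cfg: dict, outdir: str):
    params, inputs, outputs = _plan_conserve(cfg, outdir)
    alignments = read_alignment(inputs["alignment"], params["dialect"])
    if not alignments:
        raise DataError(f"{inputs['alignment']}: no alignment blocks")
    ecrs = []
    for aln in alignments:
        profile = windowed_identity(aln, params["window"])
        ecrs.extend(
            call_ecrs(profile, min_len=params["min_len"], min_identity=params["min_identity"])
        )
    if "gene_model" in inputs:
        label_ecrs(ecrs, read_gene_model(inputs["gene_model"]))
    write_bed(ecrs_to_bed(ecrs), outputs["bed"])
    # single-locus runs carry one block; the TSV includes the element sequence
    write_ecr_tsv(ecrs, alignments[0], outputs["tsv"])


def _plan_filter(cfg: dict, outdir: str):
    body = cfg.get("filter") or {}
    params = {"max_orf_aa": body.get("max_orf_aa", 20)}
    inputs = {"ecrs": os.path.join(outdir, "ecrs.tsv")}
    if body.get("annotations"):
        inputs["annotations"] = body["annotations"]
    return params, inputs, {"tsv": os.path.join(outdir, "ecrs.noncoding.tsv")}


def _exec_filter(cfg: dict, outdir: str):
    params, inputs, outputs = _plan_filter(cfg, outdir)
    if not os.path.exists(inputs["ecrs"]):
        raise DataError("filter stage requires the conserve stage output (ecrs.tsv)")
    annotations = (
        [r.interval for r in read_bed(inputs["annotations"])] if "annotations" in inputs else []
    )
    df = pd.read_csv(inputs["ecrs"], sep="\t")
    noncoding, reasons = [], []
    for row in df.itertuples(index=False):
        iv = GenomicInterval.from_1based(row.ref_chrom, int(row.ref_start), int(row.ref_end))
        call = is_noncoding(iv, str(row.sequence), annotations, max_orf_aa=params["max_orf_aa"])
        noncoding.append(str(call.noncoding).lower())
        reasons.append(";".join(call.reasons) or ".")
    df["noncoding"] = noncoding
    df["reason"] = reasons
    df.to_csv(outputs["tsv"], sep="\t", index=False)


def _plan_scan(cfg: dict, outdir: str):
    body = cfg.get("scan") or {}
    for key in ("pfm", "fasta"):
        if key not in body:
            raise ConfigError(f"scan.{key} is required for the scan stage")
    params = {
        "min_matrix_sim": body.get("min_matrix_sim", 0.80),
        "min_core_sim": body.get("min_core_sim", 0.75),
    }
    return params, {"pfm": body["pfm"], "fasta": body["fasta"]}, {
        "tsv": os.path.join(outdir, "hits.tsv")
    }


def _exec_scan(cfg: dict, outdir: str):
    params, inputs, outputs = _plan_scan(cfg, outdir)
    hits_by_seq = scan_all(
        read_fasta(inputs["fasta"]), read_pfm(inputs["pfm"]),
        params["min_matrix_sim"], params["min_core_sim"],
    )
    write_hits_tsv([h for hits in hits_by_seq.values() for h in hits], outputs["tsv"])


def _plan_frameworks(cfg: dict, outdir: str):
    body = cfg.get("frameworks") or {}
    params = {
        "tolerances": list(body.get("tolerances", [10, 15])),
        "min_tfs": body.get("min_tfs", 4),
    }
    inputs = {"hits": body.get("hits") or os.path.join(outdir, "hits.tsv")}
    outputs = {}
    for tol in params["tolerances"]:
        outputs[f"json.tol{tol}"] = os.path.join(outdir, f"frameworks.tol{tol}.json")
        outputs[f"tsv.tol{tol}"] = os.path.join(outdir, f"frameworks.tol{tol}.tsv")
    return params, inputs, outputs


def _exec_frameworks(cfg: dict, outdir: str):
    params, inputs, outputs = _plan_frameworks(cfg, outdir)
    if not os.path.exists(inputs["hits"]):
        raise DataError(
            "frameworks stage requires motif hits (scan stage output or frameworks.hits)"
        )
    by_species: dict[str, list] = {}
    for h in read_hits_tsv(inputs["hits"]):
        by_species.setdefault(h.sequence_name, []).append(h)
    for tol in params["tolerances"]:
        fws = find_frameworks(by_species, tolerance=tol, min_tfs=params["min_tfs"])
        write_frameworks_json(fws, outputs[f"json.tol{tol}"])
        write_frameworks_tsv(fws, outputs[f"tsv.tol{tol}"])


def _plan_assay(cfg: dict, outdir: str):
    body = cfg.get("assay") or {}
    if "table" not in body:
        raise ConfigError("assay.table is required for the assay stage")
    params = {
        "alpha": body.get("alpha", 0.05),
        "control": body.get("control", "prom"),
        "welch": bool(body.get("welch", False)),
        "fdr": bool(body.get("fdr", False)),
    }
    return params, {"table": body["table"]}, {"tsv": os.path.join(outdir, "assay.results.tsv")}


def _exec_assay(cfg: dict, outdir: str):
    params, inputs, outputs = _plan_assay(cfg, outdir)
    wells = read_assay_table(inputs["table"])
    results = classify_elements(
        wells, alpha=params["alpha"], control_id=params["control"],
        welch=params["welch"], fdr=params["fdr"],
    )
    write_results_tsv(results, outputs["tsv"])


_PLAN = {
    "conserve": _plan_conserve,
    "filter": _plan_filter,
    "scan": _plan_scan,
    "frameworks": _plan_frameworks,
    "assay": _plan_assay,
}
_EXEC = {
    "conserve": _exec_conserve,
    "filter": _exec_filter,
    "scan": _exec_scan,
    "frameworks": _exec_frameworks,
    "assay": _exec_assay,
}


def run_pipeline(
    config_path: str | os.PathLike,
    stages: list[str] | None = None,
    outdir: str | None = None,
) -> RunManifest:
    """Run the selected stages and write ``manifest.json`` to the outdir.

    A stage is skipped without re-execution (status ``cached``) when a
    previous manifest records identical parameters and input hashes and
    all its outputs still exist with the recorded hashes.
    """
    cfg = load_config(config_path)
    pipe = cfg.get("pipeline") or {}
    outdir = outdir or pipe.get("outdir") or "ncecr_run"
    os.makedirs(outdir, exist_ok=True)
    selected = list(stages or pipe.get("stages") or STAGES)
    for s in selected:
        if s not in STAGES:
            raise ConfigError(f"unknown stage {s!r}")
    selected = [s for s in STAGES if s in selected]  # dependency order

    manifest_path = os.path.join(outdir, "manifest.json")
    previous: dict = {}
    if os.path.exists(manifest_path):
        with open(manifest_path) as fh:
            previous = json.load(fh).get("stages", {})

    manifest = RunManifest(_hash_config(cfg), __version__, outdir, {})
    for stage in selected:
        started = _now()
        logger.info("stage %s: starting", stage)
        try:
            params, inputs, outputs = _PLAN[stage](cfg, outdir)
            prev = previous.get(stage)
            cached = (
                prev is not None
                and prev.get("params") == params
                and all(os.path.exists(p) for p in inputs.values())
                and {p: _hash_file(p) for p in inputs.values()} == prev.get("inputs")
                and all(os.path.exists(p) for p in outputs.values())
                and {p: _hash_file(p) for p in outputs.values()} == prev.get("outputs")
            )
            if not cached:
                _EXEC[stage](cfg, outdir)
        except (ConfigError, DataError):
            manifest.stages[stage] = StageRecord({}, {}, {}, "failed", started, _now())
            manifest.save(manifest_path)
            raise
        input_hashes = {p: _hash_file(p) for p in inputs.values()}
        output_hashes = {p: _hash_file(p) for p in outputs.values()}
        status = "cached" if cached else "completed"
        manifest.stages[stage] = StageRecord(
            params, input_hashes, output_hashes, status, started, _now()
        )
        logger.info("stage %s: %s", stage, status)
    manifest.save(manifest_path)
    return manifest
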