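"""End-to-end orchestration: curate, scan, calibrate, enrich, contextualise.

The per-sequence work (shuffling, folding, scoring, calibration) is a
pure function of the record and a seed derived stably from the base seed
and the record id, so serial and parallel execution give identical
results and the whole report is reproducible byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import yaml
from Bio import SeqIO

from . import __version__
from .context import hit_context, summarize_context
from .fold import get_engine
from .motif_library import curate_library, read_motif_library
from .scoring import MotifHit, calibrate_sequence, derive_seed, train_bn
from .stats import motif_enrichment, variant_table

log = logging.getLogger("perfumes")


class PipelineError(RuntimeError):
    pass


@dataclass
class RunConfig:
    pos_path: str = ""
    bg_path: str = ""
    motif_lib_path: str = ""
    out_dir: str = "perfumes_out"
    n_shuffles: int = 100
    n_samples: int = 20
    seed: int = 7
    p_threshold: float = 0.05
    alpha: float = 0.05
    adjust: str = "bh"
    test_method: str = "z"
    mode: str = "closed"
    rt: float = 1.0
    engine: str = "internal"
    workers: int = 1
    sd_floor: float = 0.05
    pseudocount: float = 1.0
    min_unique_occurrences: int = 5
    context_n_samples: int = 1000
    png: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def read_fasta(path) -> Tuple[List[Tuple[str, str]], List[str]]:
    """(id, sequence) records with T->U normalisation; ids up to first
    whitespace; duplicates rejected; non-ACGUT records skipped with a
    warning."""
    records, warnings, seen = [], [], set()
    for rec in SeqIO.parse(str(path), "fasta"):
        rid = rec.id
        if rid in seen:
            raise PipelineError(f"duplicate FASTA id {rid!r}")
        seen.add(rid)
        seq = str(rec.seq).upper().replace("T", "U")
        if set(seq) - set("ACGU"):
            warnings.append(f"record {rid!r} skipped: non-ACGU characters")
            continue
        records.append((rid, seq))
    return records, warnings


# -- deterministic parallel map -----------------------------------------

def _run_task(task, record, seed):
    return task(record, seed)


def parallel_map(task, records: Sequence[Tuple[str, str]], workers: int = 1,
                 base_seed: int = 0):
    """Apply ``task(record, derived_seed)`` to every record, preserving
    input order; per-record seeds depend only on (base_seed, record id).
    Failures are retried once, then recorded.

    Returns (results, failures) where results align with records (None
    for failed ones) and failures is a list of (record_id, message).
    """
    seeds = [derive_seed(base_seed, rid) for rid, _ in records]
    results: List[Optional[object]] = [None] * len(records)
    failures: List[Tuple[str, str]] = []
    if workers <= 1:
        for idx, (rec, sd) in enumerate(zip(records, seeds)):
            for attempt in (0, 1):
                try:
                    results[idx] = task(rec, sd)
                    break
                except Exception as e:  # noqa: BLE001 - per-record isolation
                    if attempt == 1:
                        failures.append((rec[0], str(e)))
        return results, failures
    with ProcessPoolExecutor(max_workers=workers) as pool:
        futures = [pool.submit(_run_task, task, rec, sd)
                   for rec, sd in zip(records, seeds)]
        for idx, fut in enumerate(futures):
            try:
                results[idx] = fut.result()
            except Exception:
                # retry once, locally
                try:
                    results[idx] = task(records[idx], seeds[idx])
                except Exception as e:  # noqa: BLE001
                    failures.append((records[idx][0], str(e)))
    return results, failures


@dataclass
class _CalibrateTask:
    """Picklable per-sequence calibration closure."""
    models: list
    engine: object
    n_shuffles: int
    n_samples: int
    threshold: float
    sd_floor: float

    def __call__(self, record, seed):
        rid, seq = record
        return calibrate_sequence(rid, seq, self.models, self.engine,
                                  self.n_shuffles, self.n_samples, seed,
                                  self.threshold, self.sd_floor)


# -- report --------------------------------------------------------------

def _hit_dict(h: MotifHit) -> dict:
    d = {
        "sequence_id": h.sequence_id,
        "motif_id": h.motif_id,
        # reported coordinates are 1-based inclusive
        "strand_spans": [[a + 1, b] for a, b in h.strand_spans],
        "closing_pairs": [[i + 1, j + 1] for i, j in h.closing_pair_coords],
        "score": round(float(h.score), 6),
        "variant": h.variant,
    }
    if h.p_value is not None:
        d["p_value"] = float(h.p_value)
    if h.null is not None:
        d["null"] = {"mean": round(h.null.mean, 6), "sd": round(h.null.sd, 6),
                     "n": h.null.n, "n_sentinel": h.null.n_sentinel}
    return d


def run_pipeline(cfg: RunConfig,
                 pos_records: Optional[List[Tuple[str, str]]] = None,
                 bg_records: Optional[List[Tuple[str, str]]] = None,
                 library=None) -> dict:
    """Execute the full analysis and return the (JSON-serialisable) report.

    Inputs may be passed in memory; otherwise they are read from the
    paths in ``cfg``.
    """
    warnings: List[str] = []
    if pos_records is None:
        pos_records, w = read_fasta(cfg.pos_path)
        warnings += w
    if bg_records is None:
        bg_records, w = read_fasta(cfg.bg_path)
        warnings += w
    if not pos_records or not bg_records:
        raise PipelineError("positive and background datasets must be non-empty")
    if library is None:
        library = read_motif_library(cfg.motif_lib_path)
    library = curate_library(library, cfg.min_unique_occurrences)
    if not library.motifs:
        warnings.append("motif library empty after curation")
    try:
        engine = get_engine(cfg.engine, rt=cfg.rt) if cfg.engine == "internal" \
            else get_engine(cfg.engine)
    except Exception as e:  # engine unavailable: fall back, loudly
        warnings.append(f"engine {cfg.engine!r} unavailable ({e}); "
                        "falling back to internal engine")
        log.warning(warnings[-1])
        engine = get_engine("internal", rt=cfg.rt)

    models = [train_bn(m, cfg.pseudocount) for m in library.motifs]
    task = _CalibrateTask(models, engine, cfg.n_shuffles, cfg.n_samples,
                          cfg.p_threshold, cfg.sd_floor)

    def scan(records, label):
        results, failures = parallel_map(task, records, cfg.workers,
                                         derive_seed(cfg.seed, label))
        hits = [h for r in results if r is not None for h in r]
        kept = sum(1 for r in results if r is not None)
        for rid, msg in failures:
            warnings.append(f"{label} record {rid!r} failed and was excluded: {msg}")
        return hits, kept

    hits_pos, n_pos = scan(pos_records, "positive")
    hits_bg, n_bg = scan(bg_records, "background")

    records = motif_enrichment(hits_pos, hits_bg, n_pos, n_bg, cfg.alpha,
                               cfg.adjust, cfg.test_method)
    enriched = [r for r in records if r.enriched]

    variant_tables: Dict[str, list] = {}
    context_summaries: Dict[str, list] = {}
    contexts_by_motif: Dict[str, list] = {}
    for rec in enriched:
        mid = rec.motif_id
        variant_tables[mid] = [dataclasses.asdict(v) for v in
                               variant_table(hits_pos, hits_bg, mid, n_pos, n_bg)]
        ctxs = []
        seq_by_id = dict(pos_records + bg_records)
        for h, label in ([(h, "positive") for h in hits_pos if h.motif_id == mid]
                         + [(h, "background") for h in hits_bg if h.motif_id == mid]):
            c = hit_context(seq_by_id[h.sequence_id], h, engine, cfg.mode,
                            cfg.rt, cfg.context_n_samples, cfg.seed)
            c.dataset = label
            ctxs.append(c)
        contexts_by_motif[mid] = ctxs
        context_summaries[mid] = summarize_context(ctxs)

    report = {
        "schema_version": 1,
        "tool_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "n_pos": n_pos,
        "n_bg": n_bg,
        "curation_log": [list(x) for x in library.curation_log],
        "enrichment": [dataclasses.asdict(r) for r in records],
        "enriched_motifs": [r.motif_id for r in enriched],
        "variant_tables": variant_tables,
        "context_summaries": context_summaries,
        "hits_pos": [_hit_dict(h) for h in hits_pos],
        "hits_bg": [_hit_dict(h) for h in hits_bg],
        "warnings": warnings,
    }
    report["_contexts_by_motif"] = contexts_by_motif  # stripped on write
    return report


def report_json(report: dict) -> str:
    clean = {k: v for k, v in report.items() if not k.startswith("_")}
    return json.dumps(clean, sort_keys=True, indent=1)


def write_report(report: dict, out_dir, png: bool = False) -> List[str]:
    """Write report.json (and per-enriched-motif PNG panels when asked).

    The directory must be writable; nothing is written on failure of the
    initial probe.
    """
    os.makedirs(out_dir, exist_ok=True)
    probe = os.path.join(out_dir, ".write_probe")
    try:
        with open(probe, "w") as fh:
            fh.write("")
        os.remove(probe)
    except OSError as e:
        raise PipelineError(f"output directory not writable: {e}") from e
    written = []
    path = os.path.join(out_dir, "report.json")
    with open(path, "w") as fh:
        fh.write(report_json(report))
        fh.write("\n")
    written.append(path)
    if png:
        for mid in report["enriched_motifs"]:
            written.append(_motif_figure(report, mid, out_dir))
    return written


def _motif_figure(report: dict, motif_id: str, out_dir) -> str:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ctxs = report.get("_contexts_by_motif", {}).get(motif_id, [])
    variants = report["variant_tables"].get(motif_id, [])
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5))
    names = [v["variant"] for v in variants][:8]
    x = range(len(names))
    axes[0].bar([i - 0.2 for i in x], [v["c_pos"] for v in variants][:8],
                width=0.4, label="positive")
    axes[0].bar([i + 0.2 for i in x], [v["c_bg"] for v in variants][:8],
                width=0.4, label="background")
    axes[0].set_xticks(list(x))
    axes[0].set_xticklabels(names, rotation=60, fontsize=6)
    axes[0].set_title("variant counts")
    axes[0].legend(fontsize=6)
    for ax, attr, title in ((axes[1], "mfe_constrained", "compatible MFE"),
                            (axes[2], "p_compatible", "P(compatible)")):
        data, labels = [], []
        for ds in ("positive", "background"):
            vals = [getattr(c, attr) for c in ctxs if c.dataset == ds and c.valid]
            if vals:
                data.append(vals)
                labels.append(ds)
        if data:
            ax.boxplot(data, tick_labels=labels)
        ax.set_title(title)
    fig.suptitle(motif_id)
    fig.tight_layout()
    fname = os.path.join(out_dir, motif_id.replace("&", "_") + ".png")
    fig.savefig(fname, dpi=100)
    plt.close(fig)
    return fname


def downsample(records: List[Tuple[str, str]], n: int, seed: int):
    """Seeded sampling without replacement (keeps input order)."""
    import random as _random
    if n >= len(records):
        return list(records)
    idx = sorted(_random.Random(seed).sample(range(len(records)), n))
    return [records[i] for i in idx]
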