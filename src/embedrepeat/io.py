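"""Readers and writers for every format the tool touches.

Coordinate conventions: 0-based half-open everywhere in memory; 1-based
inclusive in user-facing tables (stated in each file header).  All writers
are deterministic — identical inputs give byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .embeddings import FormatError, GroundTruth, InputError
from .repeat import DetectionResult, DetectParams

REPEAT_TABLE_COLUMNS = ["sequence_id", "iteration", "family", "instance_index",
                        "start", "end", "length", "score"]


def read_fasta(path) -> list[tuple[str, str]]:
    records = [(r.id, str(r.seq).upper()) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise InputError(f"{path}: no FASTA records")
    return records


def write_fasta(records: list[tuple[str, str]], path) -> None:
    seqs = [SeqRecord(Seq(s), id=i, description="") for i, s in records]
    SeqIO.write(seqs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Repeat table (TSV)
# ---------------------------------------------------------------------------

def write_repeat_table(results: list[DetectionResult], path) -> None:
    """One row per repeat instance; start/end are 1-based inclusive."""
    rows = []
    for res in results:
        for f, fam in enumerate(res.families):
            for k, inst in enumerate(fam.instances):
                s, e = inst.span
                rows.append([res.sequence_id, fam.iteration, f, k,
                             s + 1, e, e - s, f"{inst.score:.6f}"])
    with open(path, "w") as fh:
        fh.write("# embedrepeat repeat table; start/end 1-based inclusive\n")
        fh.write("\t".join(REPEAT_TABLE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def read_repeat_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(REPEAT_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    return df


def repeat_table_spans(df: pd.DataFrame) -> dict[str, list[tuple[int, int]]]:
    """Back to 0-based half-open spans per sequence id."""
    out: dict[str, list[tuple[int, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row.sequence_id), []).append(
            (int(row.start) - 1, int(row.end)))
    return out


# ---------------------------------------------------------------------------
# Ground truth (BED-like TSV, 0-based half-open)
# ---------------------------------------------------------------------------

def write_ground_truth(truths: list[GroundTruth], path) -> None:
    with open(path, "w") as fh:
        fh.write("# embedrepeat ground truth; start/end 0-based half-open\n")
        fh.write("sequence_id\tstart\tend\tunit_index\n")
        for t in truths:
            for k, (s, e) in enumerate(t.units):
                fh.write(f"{t.sequence_id}\t{s}\t{e}\t{k}\n")


def read_ground_truth(path) -> dict[str, GroundTruth]:
    df = pd.read_csv(path, sep="\t", comment="#")
    needed = {"sequence_id", "start", "end"}
    if not needed <= set(df.columns):
        raise FormatError(f"{path}: needs columns {sorted(needed)}")
    out: dict[str, GroundTruth] = {}
    for _, row in df.iterrows():
        sid = str(row.sequence_id)
        out.setdefault(sid, GroundTruth(sid)).units.append(
            (int(row.start), int(row.end)))
    for t in out.values():
        t.units.sort()
        t.validate()
    return out


# ---------------------------------------------------------------------------
# A2M alignments
# ---------------------------------------------------------------------------

def write_a2m(rows: list[str], headers: list[str], path) -> None:
    """A2M: uppercase = match column, lowercase = insert, '-' = deletion."""
    with open(path, "w") as fh:
        for header, row in zip(headers, rows):
            fh.write(f">{header}\n{row}\n")


def read_a2m(path) -> list[tuple[str, str]]:
    out: list[tuple[str, str]] = []
    header = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if header is not None:
                    out.append((header, "".join(chunks)))
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    if header is not None:
        out.append((header, "".join(chunks)))
    if not out:
        raise FormatError(f"{path}: no A2M records")
    return out


# ---------------------------------------------------------------------------
# JSON reports
# ---------------------------------------------------------------------------

def _params_dict(params: DetectParams) -> dict:
    d = dataclasses.asdict(params)
    return d


def detection_report(results: list[DetectionResult]) -> dict:
    report = {"tool": "embedrepeat", "results": []}
    for res in results:
        entry = {
            "sequence_id": res.sequence_id,
            "seed": res.seed,
            "parameters": _params_dict(res.params),
            "masked_spans": [[list(s) for s in spans]
                             for spans in res.masked_spans],
            "families": [],
        }
        for fam in res.families:
            entry["families"].append({
                "iteration": fam.iteration,
                "length": fam.length,
                "representative_start": fam.representative.start,
                "window_score": round(fam.representative.window_score, 6),
                "selection_metric": round(fam.selection_metric_value, 6),
                "n_instances": len(fam.instances),
                "instances": [{"start": inst.span[0] + 1, "end": inst.span[1],
                               "score": round(inst.score, 6)}
                              for inst in fam.instances],
                "msa": fam.msa,
            })
        report["results"].append(entry)
    return report


def write_json(obj: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


# ---------------------------------------------------------------------------
# Labels
# ---------------------------------------------------------------------------

def write_labels(rows: list[tuple[str, float, int]], path) -> None:
    with open(path, "w") as fh:
        fh.write("sequence_id\tprobability\tlabel\n")
        for sid, prob, label in rows:
            fh.write(f"{sid}\t{prob:.6f}\t{label}\n")


def read_labels(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sequence_id", "probability", "label"} <= set(df.columns):
        raise FormatError(f"{path}: not a label table")
    return df


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p


__all__ = [
    "read_fasta", "write_fasta", "write_repeat_table", "read_repeat_table",
    "repeat_table_spans", "write_ground_truth", "read_ground_truth",
    "write_a2m", "read_a2m", "detection_report", "write_json", "read_json",
    "write_labels", "read_labels", "ensure_dir", "REPEAT_TABLE_COLUMNS",
]
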