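"""Reading and writing the package's plain-text interchange formats.

All tables are tab-separated, header row, UTF-8, no quoting; barcodes are
uppercase.  Count tables have a first column ``barcode``; sample metadata
lives in a sidecar TSV with columns sample_id, lane_id, replicate_group,
index_sequence.  Parameter files and extraction specs are flat YAML.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd
import yaml

from .cleanup import CleanupResult, PairEvaluation
from .demux import ExtractionSpec
from .model import CleanupParams
from .multilane import BarcodeLibrary
from .tables import ReadCountTable, SampleMeta

__all__ = [
    "read_count_table", "write_count_table",
    "read_params", "write_params",
    "read_extraction_spec",
    "read_library", "write_library",
    "write_pair_evaluations", "write_prefiltered",
    "write_metrics",
]

META_COLUMNS = ["sample_id", "lane_id", "replicate_group", "index_sequence"]


def write_count_table(table: ReadCountTable, counts_path, meta_path) -> None:
    frame = table.counts.copy()
    frame.insert(0, "barcode", frame.index)
    frame.to_csv(counts_path, sep="\t", index=False)
    meta = pd.DataFrame(
        [
            {
                "sample_id": s.sample_id,
                "lane_id": s.lane_id,
                "replicate_group": s.replicate_group,
                "index_sequence": s.index_sequence or "",
            }
            for s in table.samples
        ],
        columns=META_COLUMNS,
    )
    meta.to_csv(meta_path, sep="\t", index=False)


def read_count_table(counts_path, meta_path) -> ReadCountTable:
    frame = pd.read_csv(counts_path, sep="\t", dtype={"barcode": str})
    if "barcode" not in frame.columns:
        raise ValueError(f"{counts_path}: missing 'barcode' column")
    frame = frame.set_index("barcode")
    frame.index.name = None
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).fillna("")
    samples = [
        SampleMeta(
            sample_id=row["sample_id"],
            lane_id=row.get("lane_id") or "lane1",
            replicate_group=row.get("replicate_group") or None,
            index_sequence=row.get("index_sequence") or None,
        )
        for _, row in meta.iterrows()
    ]
    ids = [s.sample_id for s in samples]
    if list(frame.columns) != ids:
        missing = set(frame.columns) ^ set(ids)
        raise ValueError(
            f"{counts_path} and {meta_path} disagree on samples: {sorted(missing)}"
        )
    return ReadCountTable(frame.astype("int64"), samples)


def write_params(params: CleanupParams, path) -> None:
    Path(path).write_text(yaml.safe_dump(params.to_dict(), sort_keys=False))


def read_params(path) -> CleanupParams:
    values = yaml.safe_load(Path(path).read_text()) or {}
    return CleanupParams.from_dict(values)


def read_extraction_spec(path) -> ExtractionSpec:
    values = yaml.safe_load(Path(path).read_text())
    return ExtractionSpec(
        primer_constant=values["primer_constant"],
        index_offset=int(values["index_offset"]),
        index_length=int(values["index_length"]),
        barcode_offset=int(values["barcode_offset"]),
        barcode_length=int(values.get("barcode_length", 15)),
        index_to_sample=dict(values["index_to_sample"]),
    )


def write_library(library: BarcodeLibrary, path) -> None:
    with open(path, "w") as handle:
        for seq in sorted(library.sequences):
            lanes = ",".join(sorted(library.provenance.get(seq, set())))
            handle.write(f"{seq}\t{lanes}\n")


def read_library(path) -> BarcodeLibrary:
    library = BarcodeLibrary()
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.split("\t")
        seq = parts[0].strip().upper()
        lanes = parts[1].split(",") if len(parts) > 1 and parts[1] else ["unknown"]
        for lane in lanes:
            library.add(seq, lane)
    return library


PAIR_COLUMNS = ["mother", "daughter", "distance", "ratio", "n_qualifying",
                "loglik", "threshold", "verdict", "reason"]


def write_pair_evaluations(pairs: Sequence[PairEvaluation], path) -> None:
    records = []
    for ev in pairs:
        score = ev.score
        records.append({
            "mother": ev.mother,
            "daughter": ev.daughter,
            "distance": ev.distance,
            "ratio": "" if score is None else score.ratio,
            "n_qualifying": "" if score is None else score.n_qualifying,
            "loglik": "" if score is None or score.loglik is None else score.loglik,
            "threshold": "" if score is None or score.threshold is None
                         else score.threshold,
            "verdict": ev.verdict,
            "reason": ev.reason or "",
        })
    pd.DataFrame(records, columns=PAIR_COLUMNS).to_csv(path, sep="\t", index=False)


def write_prefiltered(result: CleanupResult, path) -> None:
    frame = pd.DataFrame(result.removed_by_prefilter,
                         columns=["barcode", "reason"])
    frame.to_csv(path, sep="\t", index=False)


def write_metrics(counts, metrics, path) -> None:
    payload = {
        "tp": counts.tp, "fp": counts.fp, "tn": counts.tn, "fn": counts.fn,
        "sensitivity": metrics.sensitivity,
        "specificity": metrics.specificity,
        "precision": metrics.precision,
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
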