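"""CSV/JSON plumbing for trial logs, mappings, fits and assignments.

Trial-log CSV schema (one row per trial):
    subject_id,block,trial,stimulus,response,feedback
with ``stimulus`` in 1..4, ``response`` a key letter (d/f/k/l) and
``feedback`` in {0,1}.  Mappings CSV (one row per block):
    subject_id,block,s1,s2,s3,s4
with response letters.  Reading validates the schema and cross-checks
every row's feedback against the block mapping, reporting offending rows.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping as TMapping
from typing import Sequence

import numpy as np
import pandas as pd

from .comparison import AssignmentResult
from .fitting import FitResult
from .models import ModelSpec
from .task import (
    DEFAULT_CONFIG,
    Block,
    SubjectDataset,
    TaskConfig,
    TrialRecord,
    feedback_for,
)

TRIAL_COLUMNS = ["subject_id", "block", "trial", "stimulus", "response", "feedback"]


class ValidationError(ValueError):
    """A file violated the schema or the deterministic-feedback rule."""


def write_trial_log(datasets: Sequence[SubjectDataset], path: str | Path,
                    config: TaskConfig = DEFAULT_CONFIG) -> None:
    rows = []
    for ds in datasets:
        for block in ds.blocks:
            for t in block.trials:
                rows.append(
                    {
                        "subject_id": ds.subject_id,
                        "block": block.block_id,
                        "trial": t.trial_index,
                        "stimulus": t.stimulus + 1,
                        "response": config.response_labels[t.response],
                        "feedback": int(t.feedback),
                    }
                )
    pd.DataFrame(rows, columns=TRIAL_COLUMNS).to_csv(path, index=False)


def write_mappings(datasets: Sequence[SubjectDataset], path: str | Path,
                   config: TaskConfig = DEFAULT_CONFIG) -> None:
    rows = []
    for ds in datasets:
        for block in ds.blocks:
            row = {"subject_id": ds.subject_id, "block": block.block_id}
            for s, r in enumerate(block.mapping):
                row[f"s{s + 1}"] = config.response_labels[r]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_trial_log(
    trial_path: str | Path,
    mappings_path: str | Path,
    config: TaskConfig = DEFAULT_CONFIG,
) -> list[SubjectDataset]:
    """Read and validate a trial log plus its mappings file.

    Raises :class:`ValidationError` naming the offending CSV row (1-based,
    excluding the header) on any schema violation or feedback
    inconsistency.
    """
    trials = pd.read_csv(trial_path, dtype=str)
    maps = pd.read_csv(mappings_path, dtype=str)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValidationError(f"trial log missing columns {missing}")
    label_to_idx = {lab: i for i, lab in enumerate(config.response_labels)}

    mapping_of: dict[tuple[str, int], tuple[int, ...]] = {}
    for i, row in maps.iterrows():
        try:
            key = (row["subject_id"], int(row["block"]))
            mapping = tuple(label_to_idx[row[f"s{s + 1}"]] for s in range(config.n_stimuli))
        except (KeyError, ValueError) as e:
            raise ValidationError(f"mappings row {i + 1}: {e}") from e
        if sorted(mapping) != list(range(config.n_stimuli)):
            raise ValidationError(f"mappings row {i + 1}: not a permutation")
        mapping_of[key] = mapping

    datasets: dict[str, SubjectDataset] = {}
    blocks: dict[tuple[str, int], Block] = {}
    for i, row in trials.iterrows():
        rowno = i + 1
        try:
            sid = row["subject_id"]
            b = int(row["block"])
            t = int(row["trial"])
            stim = int(row["stimulus"]) - 1
            fb = int(row["feedback"])
        except (TypeError, ValueError) as e:
            raise ValidationError(f"trial log row {rowno}: {e}") from e
        if row["response"] not in label_to_idx:
            raise ValidationError(
                f"trial log row {rowno}: response {row['response']!r} not in "
                f"{config.response_labels}"
            )
        if not (0 <= stim < config.n_stimuli):
            raise ValidationError(f"trial log row {rowno}: stimulus out of range")
        if fb not in (0, 1):
            raise ValidationError(f"trial log row {rowno}: feedback must be 0 or 1")
        resp = label_to_idx[row["response"]]
        key = (sid, b)
        if key not in mapping_of:
            raise ValidationError(f"trial log row {rowno}: no mapping for subject {sid} block {b}")
        if bool(fb) != feedback_for(mapping_of[key], stim, resp):
            raise ValidationError(
                f"trial log row {rowno}: feedback inconsistent with mapping "
                f"(subject {sid}, block {b}, trial {t})"
            )
        if key not in blocks:
            blocks[key] = Block(block_id=b, mapping=mapping_of[key], trials=[])
            datasets.setdefault(sid, SubjectDataset(subject_id=sid)).blocks.append(blocks[key])
        expected = len(blocks[key].trials) + 1
        if t != expected:
            raise ValidationError(
                f"trial log row {rowno}: trial index {t}, expected {expected} "
                f"(subject {sid}, block {b})"
            )
        blocks[key].trials.append(
            TrialRecord(block_id=b, trial_index=t, stimulus=stim, response=resp, feedback=bool(fb))
        )
    for ds in datasets.values():
        ds.blocks.sort(key=lambda blk: blk.block_id)
    return list(datasets.values())


def write_fits(cohort_fits: TMapping[str, TMapping[str, FitResult]], path: str | Path) -> None:
    """fits CSV: subject_id, family, tau, alpha, order, ll_block_*, ll_total."""
    rows = []
    for sid, fits in cohort_fits.items():
        for label, fr in fits.items():
            row = {
                "subject_id": sid,
                "family": label,
                "tau": fr.spec.tau,
                "alpha": fr.spec.alpha if fr.spec.alpha is not None else "",
                "order": fr.spec.order if fr.spec.order is not None else "",
            }
            for b, ll in zip(fr.block_ids, fr.block_ll):
                row[f"ll_block_{b}"] = ll
            row["ll_total"] = fr.total_ll
            rows.append(row)
    # %.17g keeps the round-trip lossless for float64
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_fits(path: str | Path) -> dict[str, dict[str, FitResult]]:
    df = pd.read_csv(path, float_precision="round_trip")
    ll_cols = sorted(
        (c for c in df.columns if c.startswith("ll_block_")),
        key=lambda c: int(c.split("_")[-1]),
    )
    block_ids = tuple(int(c.split("_")[-1]) for c in ll_cols)
    out: dict[str, dict[str, FitResult]] = {}
    for _, row in df.iterrows():
        label = row["family"]
        alpha = row["alpha"] if "alpha" in row and pd.notna(row["alpha"]) else None
        order = row["order"] if "order" in row and pd.notna(row["order"]) else None
        if label.startswith("DRP_"):
            spec = ModelSpec("DRP", float(row["tau"]), order=str(order))
        elif label == "Q":
            spec = ModelSpec("Q", float(row["tau"]), alpha=float(alpha))
        else:
            spec = ModelSpec(label, float(row["tau"]))
        fr = FitResult(
            subject_id=row["subject_id"],
            label=label,
            spec=spec,
            block_ids=block_ids,
            block_ll=np.asarray([row[c] for c in ll_cols], dtype=float),
            total_ll=float(row["ll_total"]),
        )
        out.setdefault(row["subject_id"], {})[label] = fr
    return out


def write_assignments(assignments: Sequence[AssignmentResult], path: str | Path) -> None:
    """assignments CSV: subject_id, label, one column per test p-value."""
    keys: list[str] = []
    for a in assignments:
        for k in a.p_values:
            if k not in keys:
                keys.append(k)
    rows = []
    for a in assignments:
        row = {"subject_id": a.subject_id, "label": a.label}
        row.update({k: a.p_values.get(k, "") for k in keys})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
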