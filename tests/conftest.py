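"""Shared fixtures.

The expensive phantom evaluations (render + reconstruct + classify on the
standard 128x128x151 fixture) are computed once per session and shared by
the unit and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import golgi3d as g
from golgi3d.reconstruction import BinaryVolume, PipelineConfig


def match_records_to_truth(records, truth, tol=0.8):
    """Greedy one-to-one matching of detections to ground-truth spines by
    attachment distance; returns list of (record_idx, truth_idx)."""
    ta = np.array([s.attachment for s in truth.spines])
    matches, used = [], set()
    for i, rec in enumerate(records):
        d = np.linalg.norm(ta - np.asarray(rec.attachment), axis=1)
        j = int(np.argmin(d))
        if d[j] < tol and j not in used:
            used.add(j)
            matches.append((i, j))
    return matches


def evaluate_fixture(noise: str):
    """Run the full chain on the standard fixture; return a score dict."""
    truth, stack = g.standard_spine_fixture(noise=noise)
    cfg = PipelineConfig() if noise == "noiseless" else PipelineConfig(median_subvolume=3)
    vol, summary = g.reconstruct_spines(stack, cfg)
    rec = vol.mask[:: cfg.zfactor]
    tm = truth.mask.mask
    jaccard = (rec & tm).sum() / (rec | tm).sum()
    analysis = BinaryVolume(rec, stack.spacing)
    records, axis = g.classify_volume(analysis)
    matches = match_records_to_truth(records, truth)
    recall = len(matches) / len(truth.spines)
    precision = len(matches) / max(len(records), 1)
    per_class_n: dict[str, int] = {}
    per_class_ok: dict[str, int] = {}
    for i, j in matches:
        t = truth.spines[j].class_label
        per_class_n[t] = per_class_n.get(t, 0) + 1
        if records[i].class_label == t:
            per_class_ok[t] = per_class_ok.get(t, 0) + 1
    per_class_acc = {c: per_class_ok.get(c, 0) / n for c, n in per_class_n.items()}
    return {
        "truth": truth,
        "records": records,
        "axis": axis,
        "jaccard": float(jaccard),
        "recall": recall,
        "precision": precision,
        "per_class_accuracy": per_class_acc,
        "mean_class_accuracy": float(np.mean(list(per_class_acc.values()))),
        "density_estimate": len(records) / axis.length,
        "summary": summary,
    }


@pytest.fixture(scope="session")
def noiseless_eval():
    return evaluate_fixture("noiseless")


@pytest.fixture(scope="session")
def snr10_eval():
    return evaluate_fixture("snr10")


@pytest.fixture(scope="session")
def spindle_cell():
    return g.generate_spindle_swc(g.SpindleParams(seed=1))
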