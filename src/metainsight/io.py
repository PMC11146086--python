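"""Delimited-text interfaces.

Trial tables: CSV with columns subject_id, condition, block,
stimulus (0/1), response (0/1), confidence (float 0-100), rt_ms
(optional), imagery_check_pass (0/1).  Count tables: long-format CSV
with columns subject_id, condition, stim, resp, conf_bin, count.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from .pipeline import REQUIRED_TRIAL_COLUMNS

__all__ = [
    "read_trials",
    "write_trials",
    "read_counts",
    "write_counts",
    "load_scenario",
    "dump_scenario",
    "write_posterior_summary",
    "write_run_report",
]


def load_scenario(path):
    """Read a :class:`~metainsight.simulate.GroupScenario` from YAML/JSON.

    The file mirrors the dataclass fields, e.g.::

        insight_label: custom
        c1: {no_imagery: 0.2, imagery: 0.0}
        c2_minus: {no_imagery: -0.6, imagery: -0.8}
        c2_plus: {no_imagery: 1.0, imagery: 0.8}
        d_prime: 2.5
        m_ratio: 0.8
    """
    import yaml

    from .simulate import GroupScenario

    raw = yaml.safe_load(Path(path).read_text())  # JSON is a YAML subset
    return GroupScenario(**raw)


def dump_scenario(scenario, path) -> None:
    """Write a scenario's fields as YAML."""
    import dataclasses

    import yaml

    Path(path).write_text(
        yaml.safe_dump(dataclasses.asdict(scenario), sort_keys=False))


def read_trials(path) -> pd.DataFrame:
    trials = pd.read_csv(path)
    missing = [c for c in REQUIRED_TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return trials


def write_trials(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, index=False)


def read_counts(path) -> pd.DataFrame:
    counts = pd.read_csv(path)
    needed = ["subject_id", "condition", "stim", "resp", "conf_bin", "count"]
    missing = [c for c in needed if c not in counts.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return counts


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, index=False)


def write_posterior_summary(posterior, path) -> None:
    """Posterior summary CSV: parameter, mean, hdi_low, hdi_high, rhat, ess."""
    posterior.summary_frame().to_csv(path, index=False)


def write_run_report(path, seed, settings: dict,
                     data_frame: pd.DataFrame | None = None) -> None:
    """JSON run report: seed, settings, and a fingerprint of the data."""
    report = {"seed": seed, "settings": settings}
    if data_frame is not None:
        payload = data_frame.to_csv(index=False).encode()
        report["data_fingerprint"] = hashlib.sha256(payload).hexdigest()[:16]
        report["data_rows"] = len(data_frame)
    Path(path).write_text(json.dumps(report, indent=2, default=str) + "\n")
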