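"""Summary statistics of the discharge protocols.

Convenience layer used by the acceptance script and the regression tests:
runs a protocol over several seeds, detects discharges with the default
hysteresis detector and aggregates per-class event frequencies, interval
CVs and conductance ratios; measures the transition time to the sustained
high-activity state when depression is disabled.
"""

from __future__ import annotations

import numpy as np

from .analysis import (DetectionThresholds, conductance_ratios, detect_events,
                       event_statistics)
from .network import NetworkConfig, run_protocol

__all__ = ["measure_protocol", "transition_onset", "HIGH_ACTIVITY_HZ",
           "QUIESCENT_HZ"]

HIGH_ACTIVITY_HZ = 20.0   # interneuron rate defining the sustained state
QUIESCENT_HZ = 1.0        # return-to-rest threshold


def measure_protocol(protocol: str, seeds=(1, 2, 3), seconds_per_seed=100.0,
                     config: NetworkConfig | None = None,
                     thresholds: DetectionThresholds | None = None,
                     keep_traces: bool = False) -> dict:
    """Run a discharge protocol over several seeds and pool event statistics.

    Returns a dict with total simulated time, pooled event tables per class,
    per-class frequencies (events/s over the whole simulated time), the CV
    of inter-onset intervals per seed (pooled by averaging defined values),
    and optionally the raw traces.
    """
    cfg = config or NetworkConfig()
    thr = thresholds or DetectionThresholds()
    tables, traces, cvs = [], [], {"IID1": [], "IID2": [], "all": []}
    total_s = 0.0
    for seed in seeds:
        trace = run_protocol(protocol, cfg, seed=int(seed),
                             duration=seconds_per_seed * 1000.0)
        events = detect_events(trace, thr)
        total_s += seconds_per_seed
        tables.append(events)
        if keep_traces:
            traces.append(trace)
        for cls in ("IID1", "IID2"):
            sub = events[events["event_class"] == cls]
            st = event_statistics(sub, seconds_per_seed * 1000.0)
            if st["cv_defined"]:
                cvs[cls].append(st["cv_intervals"])
        st = event_statistics(events, seconds_per_seed * 1000.0)
        if st["cv_defined"]:
            cvs["all"].append(st["cv_intervals"])
    import pandas as pd
    pooled = pd.concat(tables, ignore_index=True) if tables else None
    counts = pooled["event_class"].value_counts().to_dict() if len(pooled) else {}
    out = {
        "protocol": protocol,
        "seeds": list(seeds),
        "total_seconds": total_s,
        "events": pooled,
        "n_events": int(len(pooled)),
        "frequency_hz": {
            "all": len(pooled) / total_s,
            "IID1": counts.get("IID1", 0) / total_s,
            "IID2": counts.get("IID2", 0) / total_s,
        },
        "cv_intervals": {k: (float(np.mean(v)) if v else float("nan"))
                         for k, v in cvs.items()},
    }
    if keep_traces:
        out["traces"] = traces
    if len(pooled):
        out["ratios"] = conductance_ratios(pooled)
    return out


def transition_onset(seed: int, duration_s: float = 5.0,
                     config: NetworkConfig | None = None) -> float | None:
    """Time (ms) of the irreversible switch to the sustained high-activity
    state with depression disabled, or None if no such switch occurs.

    The onset is the first time the interneuron rate exceeds
    ``HIGH_ACTIVITY_HZ`` without ever returning below ``QUIESCENT_HZ`` for
    the remainder of the run.
    """
    trace = run_protocol("no_depression", config or NetworkConfig(),
                         seed=int(seed), duration=duration_s * 1000.0)
    nu = trace["nu_I"]
    t = trace["time"]
    above = np.nonzero(nu > HIGH_ACTIVITY_HZ)[0]
    # suffix minimum: the earliest candidate whose future never dips to rest
    if len(above) == 0:
        return None
    suffix_min = np.minimum.accumulate(nu[::-1])[::-1]
    for i in above:
        if suffix_min[i] > QUIESCENT_HZ:
            return float(t[i])
    return None
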