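"""CSV/JSON serialisation for the null-simulation study."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd


def replicates_to_frame(replicates) -> pd.DataFrame:
    """One row per replicate; profiles expand to prof_00.. columns."""
    rows = []
    for r in replicates:
        row = {
            "replicate": r.replicate,
            "source_tree_id": r.source_tree_id,
            "sim_tree_id": r.sim_tree_id,
            "est_tree_id": r.est_tree_id,
            "true_q01": r.true_rates.q01,
            "true_q10": r.true_rates.q10,
            "est_q01": r.est.params.base.q01,
            "est_q10": r.est.params.base.q10,
            "t_shift": r.est.params.t_shift,
            "log10_r01": r.est.log10_r01,
            "log10_r10": r.est.log10_r10,
            "shift_direction_01": r.shift_direction_01,
            "shift_direction_10": r.shift_direction_10,
            "argmax_age": r.argmax_age,
            "log10_magnitude": r.log10_magnitude,
            "delta_lnL_vs_constant": r.est.delta_lnL_vs_constant,
            "delta_AIC_vs_constant": r.est.delta_AIC_vs_constant,
        }
        if r.profile_delta_lnL is not None:
            for k, v in enumerate(np.asarray(r.profile_delta_lnL)):
                row[f"prof_{k:02d}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def summary_to_json(summary, path: str) -> None:
    payload = {
        "n_ok": summary.n_ok,
        "n_failed": summary.n_failed,
        "prop_up_in_window": summary.prop_up_in_window,
        "prop_epoch_favored": summary.prop_epoch_favored,
        "boundary_old": list(summary.boundary_old),
        "mean_profile": (None if summary.mean_profile is None
                         else [float(x) for x in summary.mean_profile]),
        "profile_grid_ages": (None if summary.profile_grid_ages is None
                              else [float(x)
                                    for x in summary.profile_grid_ages]),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
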