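#!/usr/bin/env python
"""Diffusive-state HMM analysis of the simulated conditions.

Selects the number of diffusive states by BIC (up to 3), reports per-state
diffusivities, transition probabilities, occupancies and dwell times, and
re-estimates P(mobile -> less mobile) in five 12 s windows across the 60 s
tracks.  Writes results/analysis/hmm_<condition>.json.
"""

import json
from pathlib import Path

import numpy as np

from tred import io
from tred.hmm import select_state_count, windowed_transitions

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"


def main() -> None:
    for path in sorted(OUT.glob("tracks_*.csv")):
        name = path.stem.removeprefix("tracks_")
        tracks = io.read_tracks_csv(path)[:60]  # 60 tracks suffice for state structure
        dt = tracks[0].frame_interval
        model = select_state_count(tracks, 3, dt, seed=0)
        wins = (
            windowed_transitions(tracks, model, window=12.0, total=60.0)
            if model.K >= 2
            else []
        )
        payload = {
            "K": model.K,
            "labels": model.labels,
            "D_states": model.D_states.tolist(),
            "trans": np.round(model.trans, 4).tolist(),
            "occupancy": np.round(model.occupancy, 4).tolist(),
            "dwell_times_s": np.round(model.dwell_times, 3).tolist(),
            "n_tracks": model.n_tracks,
            "windowed_p_mobile_to_less": [
                {"start_s": w.window_start, "end_s": w.window_end,
                 "p": round(w.p_mobile_to_less, 4)}
                for w in wins
            ],
        }
        (OUT / f"hmm_{name}.json").write_text(json.dumps(payload, indent=2))
        print(f"{name}: K={model.K}, D={np.round(model.D_states, 5).tolist()}, "
              f"occupancy={np.round(model.occupancy, 3).tolist()}")
        if wins:
            print(f"  P(mobile->less) per 12 s window: "
                  f"{[round(w.p_mobile_to_less, 3) for w in wins]}")


if __name__ == "__main__":
    main()
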