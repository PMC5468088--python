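"""Generate a synthetic recording day and inspect its structure.

The generator emulates a session in which a monkey performs center-out
(CO) reaches and neurofeedback-then-reach (NR) trials: 1 kHz LFP with
beta bursts whose prevalence tracks the beta target, Poisson spike
trains coupled to the beta envelope, and reach kinematics whose
movement onset time depends on the preceding target.
"""

import numpy as np

from betapop import GeneratorConfig, generate_session, write_session

config = GeneratorConfig(seed=1, n_trials_co=10, n_trials_per_target=5, n_units=6)
session, truth = generate_session(config)

print(f"session {session.session_id!r}: {len(session.trials)} trials, "
      f"{len(session.lfp)} LFP channels, {len(session.spikes)} units")
print(f"duration: {session.duration_s:.1f} s at {session.fs_lfp:.0f} Hz")
n_nr = len(session.trials_by_task("NR"))
print(f"CO trials: {len(session.trials) - n_nr}, NR trials: {n_nr}")
n_bursts = sum(len(v) for v in truth.burst_intervals.values())
print(f"ground truth: {n_bursts} beta bursts, "
      f"mean true MOT {np.mean(list(truth.mot_s.values())):.3f} s")

write_session(session, "scratch/example_session")
print("written to scratch/example_session/ (signals.h5 + CSV tables)")
# The ground-truth bursts, MOTs and coupling slopes let every analysis
# stage be checked against what was actually put into the data.
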