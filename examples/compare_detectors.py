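"""Complementarity analysis of several interaction detectors.

Given per-replicate success vectors of two or three detectors (one bit per
simulated dataset: did the detector top-rank the true pair?), the analysis
cross-tabulates their failures.  The complementarity degree
CD = SF / (DF + SF) is 1 when the detectors never fail together and 0 when
one detector's successes contain the other's; the joint power counts the
replicates where at least one succeeds.
"""

import numpy as np

import epiensemble as ep

# Success counts over 100 replicates for three detectors on one condition:
# detector A succeeds on 80, B on 75, and together they cover 84.
ft = ep.fault_table_from_marginals(80, 75, 84, 100)
print("fault table: SS=%d SF=%d FS=%d FF=%d" % (ft.ss, ft.sf, ft.fs, ft.ff))
print(f"CD(A,B) = {ep.complementarity(ft):.3f}")
print(f"joint power = {ep.joint_power_pair(ft):.0f}%")
# CD ~ 0.45 means the two detectors fail on noticeably different replicates,
# so combining them lifts power from 80% to 84%.

# With full per-replicate vectors, three detectors can be combined.
rng = np.random.default_rng(0)
vectors = {
    "A": rng.random(100) < 0.80,
    "B": rng.random(100) < 0.75,
    "C": rng.random(100) < 0.70,
}
outcomes = [ep.IdentificationOutcome(n, v) for n, v in vectors.items()]
for row in ep.complementarity_table(outcomes):
    print(f"{row['pair']}: CD={row['cd']}, joint power={row['joint_power']:.0f}%")
print(f"all three: joint power = {ep.joint_power_triple(*outcomes):.0f}%")
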