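"""Profile a Y-maze turn sequence into tetragram strategies.

Builds a short hand-written turn stream, prints its 16-pattern tetragram
composition, the alternation/repetition summaries, and the per-bin profile
of a simulated one-hour session.
"""
import numpy as np

from boldmaze.simulate import LatentRecord, YmazeSimConfig, simulate_ymaze
from boldmaze.ymaze import bin_profiles, global_summary, tetragram_counts

tokens = list("LRLRLRLLLLRLRL")
profile = tetragram_counts(tokens)
print(f"sequence: {''.join(tokens)}")
print(f"turns: {profile.total_turns}, tetragrams (overlapping windows of 4): "
      f"{profile.total_tetragrams}")
for pattern, count in sorted(profile.counts.items(), key=lambda kv: -kv[1]):
    if count:
        print(f"  {pattern}: {count}  ({profile.pct[pattern]:.1f} %)")
print(f"alternations (LRLR + RLRL): {profile.alternations_pct:.1f} %  "
      "<- working-memory-linked strategy")
print(f"repetitions  (LLLL + RRRR): {profile.repetitions_pct:.1f} %  "
      "<- perseverative strategy")

print()
print("One simulated stressed fish, 60 min, 10-min bins:")
latent = LatentRecord("fish1", "bold", "CAS", "F", 0.0, a_base=0.7, peak_bin=5)
events = simulate_ymaze(latent, YmazeSimConfig(), np.random.default_rng(5))
total, alt, rep = global_summary(events)
print(f"global: {total} turns, alternations {alt:.1f} %, repetitions {rep:.1f} %")
for i, b in enumerate(bin_profiles(events, subject_id="fish1").bins, start=1):
    print(f"  bin {i} ({int(b.window[0] // 60)}-{int(b.window[1] // 60)} min): "
          f"alternations {b.alternations_pct:.1f} %, "
          f"repetitions {b.repetitions_pct:.1f} %")
print("The stress-induced repetition bump for a bold fish is centered on")
print("bin 5 (40-50 min), so repetitions should peak there.")
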