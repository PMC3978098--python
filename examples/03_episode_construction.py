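"""Group one patient's prescriptions into episodes with the 90-day rule.

A gap of up to 90 days between consecutive issues continues an episode; a
gap of 91 or more starts a new one, so 91 days is the smallest possible
spacing between episodes.
"""

import datetime as dt

from nrt_pathways import build_episodes, discontinuation, inter_episode_gaps
from nrt_pathways.records import PrescriptionEvent

index = dt.date(2009, 3, 1)
offsets_and_products = [
    (-9, "NRT_inhalator", "10 mg"),      # pre-index: merged into episode 1
    (0, "NRT_patch", "21 mg/24 hours"),  # the index prescription
    (28, "NRT_patch", "21 mg/24 hours"),
    (118, "NRT_patch", "21 mg/24 hours"),   # gap 90 -> same episode
    (300, "NRT_patch", "15 mg/16 hours"),   # gap 182 -> new episode
]
events = [
    PrescriptionEvent("p1", index + dt.timedelta(days=o), c, s)
    for o, c, s in offsets_and_products
]

episodes = build_episodes(events, index)
for ep in episodes:
    print(
        f"episode {ep.ordinal}: {ep.start_date} .. {ep.end_date} "
        f"({len(ep.events)} issues, classes={sorted(ep.class_set)})"
    )
print("inter-episode gaps (days):", inter_episode_gaps(episodes))

followup_end = dt.date(2010, 6, 30)
status = discontinuation(episodes, followup_end)
print(f"discontinued by {followup_end}: {status.discontinued}")

# Episode 1 keeps the index date as its anchor even though the inhalator
# was issued nine days earlier; the 182-day gap opens episode 2, and the
# quiet tail after it (>90 days before follow-up end) marks
# discontinuation of prescribed NRT.
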