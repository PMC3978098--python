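"""Classify episode regimens and derive first-line/add-on pathways.

A regimen category depends only on the set of NRT types in an episode
(patch-only, patch+partner, three or more types, or patch-free "other"
categories).  The pathway view distinguishes products present at episode
start (first-line) from products added later.
"""

import datetime as dt

from nrt_pathways import build_episodes, classify_episode, pathway_decompose
from nrt_pathways.records import PrescriptionEvent
from nrt_pathways.regimens import decompose_patient, pathway_signature, product_display

index = dt.date(2009, 3, 1)
events = [
    PrescriptionEvent("p1", index, "NRT_patch", "21 mg/24 hours"),
    PrescriptionEvent("p1", index + dt.timedelta(days=30), "NRT_patch", "14 mg/24 hours"),
    PrescriptionEvent("p1", index + dt.timedelta(days=45), "NRT_patch", "7 mg/24 hours"),
]
(episode,) = build_episodes(events, index)

print("category:", classify_episode(episode.class_set))
entry = pathway_decompose(episode)
print("first-line:", [product_display(c, s) for c, s in entry.first_line])
print("add-on:    ", [product_display(c, s) for c, s in entry.add_on])
print("signature: ", pathway_signature(decompose_patient("p1", [episode])))

# Three patch strengths are still one NRT *type*, so the category stays
# patch_only; the step-down strengths appear as add-ons in issue order,
# and the canonical signature is stable under input-row reshuffling.
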