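"""Collapse coded images into exposure episodes with the 30-s timeout rule.

An exposure episode starts at the first image bearing a (setting, medium,
product) code and ends once more than 30 s passes without another image of
the same code. A tiny hand-built stream shows the rule's behaviour at the
boundary.
"""

import pandas as pd

from camexposure import segment

t0 = pd.Timestamp("2015-03-05T09:00:00")
rows = []
# same code at 0, 7, 14 s -> one episode; again at 60 s (gap 46 > 30) -> a second
for s in (0, 7, 14, 60):
    rows.append(("c1", t0 + pd.Timedelta(seconds=s), "home", "sign", "fast_food"))
# one image carrying a second, different code -> its own episode
rows.append(("c1", t0, "home", "product_packaging", "sugary_drinks"))
coded = pd.DataFrame(rows, columns=["child_id", "timestamp", "setting", "medium", "product"])

episodes = segment(coded, timeout=30, permissive=True)
print(episodes.to_string(index=False))
print()
print(f"{len(episodes)} episodes: the 46-s gap splits the fast-food sign into two,")
print("and the multi-coded first image contributes to a separate sugary-drinks episode.")

# a gap of exactly 30 s continues the episode under the default boundary rule
boundary = segment(coded.iloc[:2].assign(
    timestamp=[t0, t0 + pd.Timedelta(seconds=30)]), timeout=30)
print(f"gap of exactly 30 s -> {len(boundary)} episode (the rule closes only after 30 s has elapsed)")
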