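"""The push/push-back rule on a constructed two-field collision.

Field B has been driven 5 px into field A's frozen pre-collision shape. A's
interface points inside its own predicted region authorize it to push back:
it reclaims the dent, and B's level-set sign is switched to positive
(exterior) on the reclaimed pixels. The printed areas show A restored to its
recorded shape.
"""

import numpy as np

from rhizotrace import LevelSetField
from rhizotrace.collisions import classify_points, resolve_push

yy, xx = np.ogrid[0:96, 0:96]


def disc(cy, cx, r):
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2


pred_a = disc(48, 30, 12)      # A's shape, recorded before the collision
pred_b = disc(48, 54, 12)      # B's shape, recorded just touching A
b_mask = disc(48, 49, 12)      # B has advanced 5 px into A
a_mask = pred_a & ~b_mask      # A dented accordingly

a = LevelSetField(1, 1, a_mask)
b = LevelSetField(2, 2, b_mask)
states_a = classify_points(a, pred_a)
n_inside = sum(s.inside_predicted for s in states_a)
print(f"A before push-back: {a.area} px of its {int(pred_a.sum())} px shape; "
      f"{n_inside} interface points lie inside the predicted region")

a2, b2, contested = resolve_push(a, b, states_a,
                                 classify_points(b, pred_b), pred_a, pred_b)
print(f"contested pixels: {contested}")
print(f"A after push-back : {a2.area} px "
      f"({a2.area / pred_a.sum():.1%} of its predicted shape)")
reclaimed = pred_a & b_mask & ~pred_b
print(f"reclaimed from B  : {int(reclaimed.sum())} px, all now interior to A "
      f"({bool(a2.mask[reclaimed].all())}) and exterior to B "
      f"({not b2.mask[reclaimed].any()})")
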