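"""Canonical channel and marker naming for the lunge protocol.

Thirteen ipsilateral (stepping-limb) surface EMG channels and the subset of
reflective markers the implemented algorithms require. Muscle order is fixed
package-wide: every muscles-by-time matrix uses exactly this row order.
"""

from __future__ import annotations

#: Canonical 13-muscle order: gluteus medius, gluteus maximus, tensor fasciae
#: latae, rectus femoris, vastus medialis, vastus lateralis, semitendinosus,
#: biceps femoris (long head), tibialis anterior, peroneus longus,
#: gastrocnemius medialis, gastrocnemius lateralis, soleus.
MUSCLES: tuple[str, ...] = (
    "ME", "MA", "FL", "RF", "VM", "VL", "ST",
    "BF", "TA", "PL", "GM", "GL", "SO",
)

N_MUSCLES: int = len(MUSCLES)

#: Markers needed by the joint-angle and event-detection algorithms.
REQUIRED_MARKERS: tuple[str, ...] = (
    "greater_trochanter",
    "lateral_epicondyle",
    "lateral_malleolus",
    "calcaneus",
    "fifth_metatarsal",
    "toe_tip",
)

# Functional groupings used by the coactivation indices (antagonist / agonist)
HIP_ANTAGONISTS = ("FL", "RF")
HIP_AGONISTS = ("ME", "MA")
KNEE_ANTAGONISTS = ("BF", "ST")
KNEE_AGONISTS = ("RF", "VM", "VL")
ANKLE_ANTAGONISTS = ("TA",)
ANKLE_AGONISTS = ("GM", "GL", "SO")
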