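"""Default sensory-modality and motor-domain vocabularies.

These follow the annotation scheme of insect CNS connectomes: sensory
neurons are grouped by modality class, motor neurons by the body part
(domain) they innervate.  All pipeline stages accept custom vocabularies;
these are only the defaults used by the synthetic generators and the
behaviour-compatibility rules.
"""

DEFAULT_MODALITIES = [
    "olfaction",
    "gustatory",
    "vision",
    "mechanosensory",
    "tactile",
    "proprioceptive",
]

DEFAULT_DOMAINS = [
    "proboscis",
    "neck",
    "front_leg",
    "middle_leg",
    "hind_leg",
    "wings",
    "halteres",
    "abdominal",
]

#: domains counted as "legs" by the behaviour rules
LEG_DOMAINS = ["front_leg", "middle_leg", "hind_leg"]

#: modalities counted as "mechanosensory" in the broad sense
MECHANOSENSORY_GROUP = ["mechanosensory", "tactile", "proprioceptive"]
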