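"""Species and activity vocabularies shared across the pipeline.

Volunteer observers could tick any of seven raptor species plus two
non-raptor "lookalike" groups (corvids, gulls) whose silhouettes may
trigger the same anti-predator response at dusk. For each species present
they recorded one of four activity levels.
"""

RAPTOR_SPECIES: tuple[str, ...] = (
    "kestrel",
    "peregrine",
    "sparrowhawk",
    "red_kite",
    "buzzard",
    "harrier",
    "owl",
)

#: Non-raptor groups recorded because they can be mistaken for predators.
LOOKALIKE_SPECIES: tuple[str, ...] = ("corvid", "gull")

PREDATOR_SPECIES: tuple[str, ...] = RAPTOR_SPECIES + LOOKALIKE_SPECIES

#: Activity categories, escalating from passive presence to direct engagement
#: (flying through the flock or making a strike).
ACTIVITIES: tuple[str, ...] = ("perch_silent", "perch_calling", "flying", "engaging")

ABSENT = "absent"

RECENCY_CATEGORIES: tuple[str, ...] = ("today", "within_week", "within_month", "over_month")

#: "other" covers partial roosting / flock splitting; "unknown" is only
#: valid when the end of the event was not witnessed.
ENDINGS: tuple[str, ...] = ("roost_en_masse", "dispersed", "other", "unknown")
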