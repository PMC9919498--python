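"""Stage and event codings for the two-sex multievent model.

Females occupy eight states: juvenile (``Juv``), prebreeder (``Pb``),
breeder with a young-of-the-year (``By``), breeder with a 1-, 2- or
3-year-old calf (``Bc1``-``Bc3``), nonbreeder (``Nb``) and dead.  Males
occupy five: juvenile, subadult (``Sub``), not-toothed adult (``AdNt``),
toothed adult (``Ad``) and dead.  Calves and young-of-the-year are not
states of their own -- the presence of dependent young is an attribute of
the mother's state.

Observed events are integer codes; 1 is "not seen" for both sexes.  The
ambiguous codes are 7 for females ("seen alone", a prebreeder or a
nonbreeder that could not be told apart) and 6 for males ("seen as
adult", toothed status not ascertained).
"""

from __future__ import annotations

FEMALE_STAGES = ("Juv", "Pb", "By", "Bc1", "Bc2", "Bc3", "Nb")
MALE_STAGES = ("Juv", "Sub", "AdNt", "Ad")

#: living-state index helpers (dead state is always last)
F_JUV, F_PB, F_BY, F_BC1, F_BC2, F_BC3, F_NB = range(7)
F_DEAD = 7
M_JUV, M_SUB, M_ADNT, M_AD = range(4)
M_DEAD = 4

N_FEMALE_STATES = 8   # 7 living + dead
N_MALE_STATES = 5     # 4 living + dead
N_FEMALE_EVENTS = 7
N_MALE_EVENTS = 6

#: order of the 11 counted stage cells used throughout (females then males)
COUNTED_STAGES = tuple(f"{s}_F" for s in FEMALE_STAGES) + tuple(
    f"{s}_M" for s in MALE_STAGES
)
N_COUNTED = 11

#: offsets of the two sex blocks inside the 11-cell counted vector
FEMALE_BLOCK = slice(0, 7)
MALE_BLOCK = slice(7, 11)

EVENT_NOT_SEEN = 1

FEMALE_EVENT_LABELS = {
    1: "not seen",
    2: "seen as juvenile",
    3: "seen as prebreeder",
    4: "seen as breeder with a young-of-the-year",
    5: "seen as breeder with a 1-year-old or older calf",
    6: "seen as nonbreeder",
    7: "seen alone",
}

MALE_EVENT_LABELS = {
    1: "not seen",
    2: "seen as juvenile",
    3: "seen as subadult",
    4: "seen as not toothed adult",
    5: "seen as toothed adult",
    6: "seen as adult",
}
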