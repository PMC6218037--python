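"""Frailty states and their ordering.

States are ordered by severity: robust < pre-frail < frail. The integer codes
are used internally for transition matrices; the string labels appear in all
tabular output.
"""

ROBUST = "robust"
PREFRAIL = "prefrail"
FRAIL = "frail"

#: Severity order; index doubles as the integer code.
STATES = (ROBUST, PREFRAIL, FRAIL)

STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def state_index(state: str) -> int:
    """Integer severity code of a state label (robust=0, prefrail=1, frail=2)."""
    try:
        return STATE_INDEX[state]
    except KeyError:
        raise ValueError(f"unknown frailty state {state!r}; expected one of {STATES}")
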