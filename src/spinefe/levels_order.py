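"""Canonical thoracolumbar level ordering shared across modules."""

LEVEL_ORDER = tuple(f"T{i}" for i in range(1, 13)) + tuple(f"L{i}" for i in range(1, 7))


def level_index(level: str) -> int:
    try:
        return LEVEL_ORDER.index(level)
    except ValueError:
        raise ValueError(f"unknown vertebral level '{level}'") from None


def adjacent_pairs(levels=LEVEL_ORDER):
    """(upper, lower) pairs of anatomically adjacent levels, cranial first."""
    ordered = sorted(set(levels), key=level_index)
    return [
        (a, b)
        for a, b in zip(ordered, ordered[1:])
        if level_index(b) == level_index(a) + 1
    ]
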