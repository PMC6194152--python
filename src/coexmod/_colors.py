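"""Size-ranked module colour labels (largest module first), WGCNA convention."""

MODULE_COLORS = [
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
]


def color_label(rank: int) -> str:
    """Label for the module of size-rank ``rank`` (0 = largest)."""
    if rank < len(MODULE_COLORS):
        return MODULE_COLORS[rank]
    return f"module{rank + 1}"
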