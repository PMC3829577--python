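"""Embedded stroke-vector font.

Each glyph is a list of polylines on a nominal 8-wide x 12-high grid
(y up, origin bottom-left).  Deliberately minimal — single-stroke capitals
and digits good enough for procedurally generated test imagery — so the
package renders identically everywhere with no system-font dependency.
"""

# glyph -> list of polylines, each polyline a list of (x, y)
GLYPH_STROKES: dict[str, list[list[tuple[float, float]]]] = {
    "A": [[(0, 0), (4, 12), (8, 0)], [(1.7, 5), (6.3, 5)]],
    "B": [
        [(0, 0), (0, 12), (5, 12), (7, 10.5), (7, 7.5), (5, 6), (0, 6)],
        [(5, 6), (7, 4.5), (7, 1.5), (5, 0), (0, 0)],
    ],
    "C": [
        [(7, 10), (5, 12), (3, 12), (1, 10), (0, 8), (0, 4), (1, 2), (3, 0),
         (5, 0), (7, 2)],
    ],
    "D": [[(0, 0), (0, 12), (4, 12), (7, 9), (7, 3), (4, 0), (0, 0)]],
    "E": [[(7, 12), (0, 12), (0, 0), (7, 0)], [(0, 6), (5, 6)]],
    "F": [[(7, 12), (0, 12), (0, 0)], [(0, 6), (5, 6)]],
    "G": [
        [(7, 10), (5, 12), (3, 12), (1, 10), (0, 8), (0, 4), (1, 2), (3, 0),
         (5, 0), (7, 2), (7, 5), (4, 5)],
    ],
    "H": [[(0, 0), (0, 12)], [(8, 0), (8, 12)], [(0, 6), (8, 6)]],
    "I": [[(4, 0), (4, 12)], [(2, 12), (6, 12)], [(2, 0), (6, 0)]],
    "J": [[(6, 12), (6, 2), (4, 0), (2, 0), (0, 2)]],
    "K": [[(0, 0), (0, 12)], [(0, 5), (7, 12)], [(2.5, 7.5), (7, 0)]],
    "L": [[(0, 12), (0, 0), (7, 0)]],
    "M": [[(0, 0), (0, 12), (4, 6), (8, 12), (8, 0)]],
    "N": [[(0, 0), (0, 12), (8, 0), (8, 12)]],
    "O": [
        [(2, 0), (6, 0), (8, 3), (8, 9), (6, 12), (2, 12), (0, 9), (0, 3),
         (2, 0)],
    ],
    "P": [[(0, 0), (0, 12), (5, 12), (7, 10), (7, 8), (5, 6), (0, 6)]],
    "Q": [
        [(2, 0), (6, 0), (8, 3), (8, 9), (6, 12), (2, 12), (0, 9), (0, 3),
         (2, 0)],
        [(5, 4), (8, 0)],
    ],
    "R": [
        [(0, 0), (0, 12), (5, 12), (7, 10), (7, 8), (5, 6), (0, 6)],
        [(3, 6), (7, 0)],
    ],
    "S": [
        [(7, 10), (5, 12), (2, 12), (0, 10), (0, 8), (2, 6), (5, 6), (7, 4),
         (7, 2), (5, 0), (2, 0), (0, 2)],
    ],
    "T": [[(0, 12), (8, 12)], [(4, 12), (4, 0)]],
    "U": [[(0, 12), (0, 3), (2, 0), (6, 0), (8, 3), (8, 12)]],
    "V": [[(0, 12), (4, 0), (8, 12)]],
    "W": [[(0, 12), (2, 0), (4, 8), (6, 0), (8, 12)]],
    "X": [[(0, 0), (8, 12)], [(0, 12), (8, 0)]],
    "Y": [[(0, 12), (4, 6), (8, 12)], [(4, 6), (4, 0)]],
    "Z": [[(0, 12), (8, 12), (0, 0), (8, 0)]],
    "0": [
        [(2, 0), (6, 0), (8, 3), (8, 9), (6, 12), (2, 12), (0, 9), (0, 3),
         (2, 0)],
        [(1.5, 2.5), (6.5, 9.5)],
    ],
    "1": [[(2, 9), (4, 12), (4, 0)], [(2, 0), (6, 0)]],
    "2": [[(0, 10), (2, 12), (5, 12), (7, 10), (7, 8), (0, 0), (7, 0)]],
    "3": [
        [(0, 11), (2, 12), (5, 12), (7, 10), (7, 8), (5, 6.5), (3, 6.5)],
        [(5, 6.5), (7, 5), (7, 2), (5, 0), (2, 0), (0, 1)],
    ],
    "4": [[(6, 0), (6, 12), (0, 4), (8, 4)]],
    "5": [
        [(7, 12), (0, 12), (0, 7), (4, 7), (7, 5), (7, 2), (5, 0), (2, 0),
         (0, 1)],
    ],
    "6": [
        [(6, 12), (1, 6), (0, 3), (2, 0), (5, 0), (7, 2), (7, 4), (5, 6),
         (2, 6), (0, 4)],
    ],
    "7": [[(0, 12), (8, 12), (3, 0)]],
    "8": [
        [(4, 6), (2, 6), (0, 8), (0, 10), (2, 12), (6, 12), (8, 10), (8, 8),
         (6, 6), (4, 6), (2, 6), (0, 4), (0, 2), (2, 0), (6, 0), (8, 2),
         (8, 4), (6, 6), (4, 6)],
    ],
    "9": [
        [(2, 0), (7, 6), (8, 9), (6, 12), (3, 12), (1, 10), (1, 8), (3, 6),
         (6, 6), (8, 8)],
    ],
}

GLYPH_WIDTH = 8.0
GLYPH_HEIGHT = 12.0
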