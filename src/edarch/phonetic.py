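"""Classic Metaphone phonetic encoding (Philips, 1990).

Used by the search module for fuzzy ("sounds-like") metadata queries:
two tokens match phonetically when their Metaphone codes are equal,
e.g. ``smith`` and ``smyth`` both encode to ``SM0`` (``0`` is the code
for the *th* sound).

The encoder covers the standard rule set for English consonant sounds;
non-ASCII letters are stripped before encoding.
"""

from __future__ import annotations

_VOWELS = frozenset("AEIOU")


def _is_vowel(word: str, i: int) -> bool:
    return 0 <= i < len(word) and word[i] in _VOWELS


def metaphone(word: str) -> str:
    """Return the Metaphone code of *word* (empty string for no letters)."""
    w = "".join(c for c in word.upper() if "A" <= c <= "Z")
    if not w:
        return ""

    # Initial-letter transformations.
    if w[:2] in ("AE", "GN", "KN", "PN", "WR"):
        w = w[1:]
    elif w[:1] == "X":
        w = "S" + w[1:]
    elif w[:2] == "WH":
        w = "W" + w[2:]

    n = len(w)
    out: list[str] = []
    i = 0
    while i < n:
        c = w[i]
        # Skip doubled letters except C (e.g. "LL" -> one L).
        if c != "C" and i > 0 and w[i - 1] == c:
            i += 1
            continue
        nxt = w[i + 1] if i + 1 < n else ""
        nxt2 = w[i + 2] if i + 2 < n else ""

        if c in _VOWELS:
            if i == 0:
                out.append(c)
        elif c == "B":
            # Silent terminal B after M ("dumb", "thumb").
            if not (i == n - 1 and i > 0 and w[i - 1] == "M"):
                out.append("B")
        elif c == "C":
            if nxt == "I" and nxt2 == "A":  # -CIA- -> X
                out.append("X")
            elif nxt == "H":
                # -SCH- -> K, otherwise CH -> X
                out.append("K" if i > 0 and w[i - 1] == "S" else "X")
                i += 1
            elif nxt in ("I", "E", "Y"):
                # -SCI/SCE/SCY-: C is silent; else soft C -> S
                if not (i > 0 and w[i - 1] == "S"):
                    out.append("S")
            else:
                out.append("K")
        elif c == "D":
            if nxt == "G" and nxt2 in ("E", "Y", "I"):  # -DGE- -> J
                out.append("J")
                i += 1
            else:
                out.append("T")
        elif c == "F":
            out.append("F")
        elif c == "G":
            if nxt == "H":
                # GH: pronounced K only before a vowel; silent otherwise
                # ("night", "weigh").
                if _is_vowel(w, i + 2):
                    out.append("K")
                i += 1
            elif nxt == "N":
                # Silent in -GN/-GNED ("sign", "signed").
                if i + 2 == n or w[i + 2 :] == "ED":
                    pass
                else:
                    out.append("K")
            elif nxt in ("I", "E", "Y"):
                out.append("J")
            else:
                out.append("K")
        elif c == "H":
            # H audible between vowel and consonant only when after vowel
            # and before vowel; silent after C,S,P,T,G handled via their rules.
            if _is_vowel(w, i - 1) and not _is_vowel(w, i + 1):
                pass
            elif i > 0 and w[i - 1] in "CSPTG":
                pass
            else:
                out.append("H")
        elif c == "J":
            out.append("J")
        elif c == "K":
            # Silent after C ("back" -> K once via C).
            if not (i > 0 and w[i - 1] == "C"):
                out.append("K")
        elif c in ("L", "M", "N", "R"):
            out.append(c)
        elif c == "P":
            if nxt == "H":
                out.append("F")
                i += 1
            else:
                out.append("P")
        elif c == "Q":
            out.append("K")
        elif c == "S":
            if nxt == "H":
                out.append("X")
                i += 1
            elif nxt == "I" and nxt2 in ("O", "A"):  # -SIO-, -SIA- -> X
                out.append("X")
            else:
                out.append("S")
        elif c == "T":
            if nxt == "H":
                out.append("0")  # the 'th' sound
                i += 1
            elif nxt == "I" and nxt2 in ("O", "A"):  # -TIO-, -TIA- -> X
                out.append("X")
            else:
                out.append("T")
        elif c == "V":
            out.append("F")
        elif c == "W":
            if _is_vowel(w, i + 1):
                out.append("W")
        elif c == "X":
            out.append("KS")
        elif c == "Y":
            if _is_vowel(w, i + 1):
                out.append("Y")
        elif c == "Z":
            out.append("S")
        i += 1
    return "".join(out)
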