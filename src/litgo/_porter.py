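"""Porter stemming algorithm (Porter 1980), suffix-stripping for English.

Direct implementation of the five-step algorithm, including the author's
later minor revisions to step 2 (``bli``/``logi``).  Tokens shorter than
three characters are returned unchanged, as in the reference code.
"""

from __future__ import annotations

_VOWELS = "aeiou"


class _Stemmer:
    """Mutable word buffer; mirrors the reference implementation's b/k/j."""

    __slots__ = ("b", "k", "j")

    def __init__(self, word: str) -> None:
        self.b = word
        self.k = len(word) - 1
        self.j = 0

    def cons(self, i: int) -> bool:
        ch = self.b[i]
        if ch in _VOWELS:
            return False
        if ch == "y":
            return True if i == 0 else not self.cons(i - 1)
        return True

    def m(self) -> int:
        # number of VC sequences in b[0..j]
        n = 0
        i = 0
        while True:
            if i > self.j:
                return n
            if not self.cons(i):
                break
            i += 1
        i += 1
        while True:
            while True:
                if i > self.j:
                    return n
                if self.cons(i):
                    break
                i += 1
            i += 1
            n += 1
            while True:
                if i > self.j:
                    return n
                if not self.cons(i):
                    break
                i += 1
            i += 1

    def vowelinstem(self) -> bool:
        return any(not self.cons(i) for i in range(self.j + 1))

    def doublec(self, j: int) -> bool:
        return j >= 1 and self.b[j] == self.b[j - 1] and self.cons(j)

    def cvc(self, i: int) -> bool:
        if i < 2 or not self.cons(i) or self.cons(i - 1) or not self.cons(i - 2):
            return False
        return self.b[i] not in "wxy"

    def ends(self, s: str) -> bool:
        length = len(s)
        if length > self.k + 1:
            return False
        if self.b[self.k - length + 1 : self.k + 1] != s:
            return False
        self.j = self.k - length
        return True

    def setto(self, s: str) -> None:
        self.b = self.b[: self.j + 1] + s
        self.k = len(self.b) - 1

    def r(self, s: str) -> None:
        if self.m() > 0:
            self.setto(s)

    # -- the five steps ----------------------------------------------------

    def step1ab(self) -> None:
        if self.b[self.k] == "s":
            if self.ends("sses"):
                self.k -= 2
            elif self.ends("ies"):
                self.setto("i")
            elif self.b[self.k - 1] != "s":
                self.k -= 1
        if self.ends("eed"):
            if self.m() > 0:
                self.k -= 1
        elif (self.ends("ed") or self.ends("ing")) and self.vowelinstem():
            self.k = self.j
            if self.ends("at"):
                self.setto("ate")
            elif self.ends("bl"):
                self.setto("ble")
            elif self.ends("iz"):
                self.setto("ize")
            elif self.doublec(self.k):
                self.k -= 1
                if self.b[self.k] in "lsz":
                    self.k += 1
            elif self.m() == 1 and self.cvc(self.k):
                self.setto("e")

    def step1c(self) -> None:
        if self.ends("y") and self.vowelinstem():
            self.b = self.b[: self.k] + "i" + self.b[self.k + 1 :]

    _STEP2 = (
        ("ational", "ate"), ("tional", "tion"), ("enci", "ence"), ("anci", "ance"),
        ("izer", "ize"), ("bli", "ble"), ("alli", "al"), ("entli", "ent"),
        ("eli", "e"), ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
        ("ator", "ate"), ("alism", "al"), ("iveness", "ive"), ("fulness", "ful"),
        ("ousness", "ous"), ("aliti", "al"), ("iviti", "ive"), ("biliti", "ble"),
        ("logi", "log"),
    )

    def step2(self) -> None:
        for suffix, repl in self._STEP2:
            if self.ends(suffix):
                self.r(repl)
                return

    _STEP3 = (
        ("icate", "ic"), ("ative", ""), ("alize", "al"), ("iciti", "ic"),
        ("ical", "ic"), ("ful", ""), ("ness", ""),
    )

    def step3(self) -> None:
        for suffix, repl in self._STEP3:
            if self.ends(suffix):
                self.r(repl)
                return

    _STEP4 = (
        "al", "ance", "ence", "er", "ic", "able", "ible", "ant", "ement",
        "ment", "ent", "ion", "ou", "ism", "ate", "iti", "ous", "ive", "ize",
    )

    def step4(self) -> None:
        for suffix in self._STEP4:
            if self.ends(suffix):
                if suffix == "ion" and not (self.j >= 0 and self.b[self.j] in "st"):
                    continue
                if self.m() > 1:
                    self.k = self.j
                return

    def step5(self) -> None:
        self.j = self.k
        if self.b[self.k] == "e":
            a = self.m()
            if a > 1 or (a == 1 and not self.cvc(self.k - 1)):
                self.k -= 1
        if self.b[self.k] == "l" and self.doublec(self.k) and self.m() > 1:
            self.k -= 1

    def run(self) -> str:
        if self.k <= 1:
            return self.b
        self.step1ab()
        self.step1c()
        self.step2()
        self.step3()
        self.step4()
        self.step5()
        return self.b[: self.k + 1]


def porter_stem(word: str) -> str:
    """Return the Porter stem of a lowercase word."""
    return _Stemmer(word).run()
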