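"""Propositional scoring of free-recall transcripts.

Discourse content is represented as predicate–argument propositions in
the Kintsch / Turner–Greene tradition: a proposition has a predicate
lemma and arguments that are either atomic lemmas (content words) or
references to other propositions. Nesting induces a hierarchy that is
collapsed to three levels:

* **main** — topic-bearing propositions (flagged as roots of the bank);
* **mid** — propositions taking at least one main proposition as an
  argument;
* **detail** — everything else (propositions embellishing mid-level or
  other minor propositions).

Recall scoring is binary with no half credit: a proposition is counted
as recalled when its predicate and every atomic argument appear in the
lemmatized transcript, either directly or through the bank's explicit
synonym lexicon. Matching is bag-of-lemmas over the whole transcript —
free recall is order-free. Propositional arguments carry no extra
lexical requirement; they are scored independently as their own
propositions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from graphlib import CycleError, TopologicalSorter

import pandas as pd

LEVELS = ("detail", "mid", "main")

#: Numeric hierarchy score used in contrasts and random slopes.
LEVEL_X = {"detail": -1, "mid": 0, "main": 1}

_VOWELS = set("aeiou")

# Irregular forms the suffix stripper would mangle.
_LEMMA_EXCEPTIONS = {
    "was": "be", "were": "be", "is": "be", "are": "be", "been": "be",
    "has": "have", "had": "have", "having": "have",
    "went": "go", "gone": "go", "goes": "go",
    "said": "say", "says": "say",
    "made": "make", "making": "make",
    "men": "man", "women": "woman", "children": "child", "people": "person",
}


def _measure(stem: str) -> int:
    """Porter-style measure: number of vowel→consonant transitions."""
    m = 0
    prev_vowel = False
    for ch in stem:
        is_vowel = ch in _VOWELS
        if prev_vowel and not is_vowel:
            m += 1
        prev_vowel = is_vowel
    return m


def _ends_cvc(stem: str) -> bool:
    if len(stem) < 3:
        return False
    c2, v, c1 = stem[-3], stem[-2], stem[-1]
    return c2 not in _VOWELS and v in _VOWELS and c1 not in _VOWELS and c1 not in "wxy"


def lemmatize(token: str) -> str:
    """Deterministic suffix-stripping lemmatizer.

    Lowercases, strips punctuation, handles plural -s/-es and verbal
    -ed/-ing with consonant-undoubling (running -> run) and Porter-style
    final-e restoration (liked -> like). A small irregular table covers
    common forms. Intentionally lightweight and swappable; it is not a
    full morphological analyzer, just a stable normalizer applied
    identically to bank lemmas and transcript tokens.
    """
    w = token.lower().strip(".,;:!?\"'()[]")
    if not w:
        return w
    if w in _LEMMA_EXCEPTIONS:
        return _LEMMA_EXCEPTIONS[w]
    if w.endswith("ies") and len(w) > 4:
        return w[:-3] + "y"
    if w.endswith(("sses", "shes", "ches", "xes")):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us")) and len(w) > 3:
        w = w[:-1]
    for suffix in ("ing", "ed"):
        if w.endswith(suffix) and len(w) > len(suffix) + 2:
            stem = w[: -len(suffix)]
            if len(stem) >= 3 and stem[-1] == stem[-2] and stem[-1] not in _VOWELS:
                return stem[:-1]
            if _measure(stem) == 1 and _ends_cvc(stem):
                return stem + "e"
            return stem
    return w


@dataclass(frozen=True)
class Proposition:
    """A predicate–argument unit; args are atomic lemmas or proposition ids."""

    id: str
    predicate: str
    args: tuple[str, ...]
    level: str | None = None

    def __post_init__(self) -> None:
        if len(self.args) == 0:
            raise ValueError(f"proposition {self.id}: args must be non-empty")
        object.__setattr__(self, "args", tuple(self.args))


@dataclass(frozen=True)
class RecallScore:
    """Per-level recall counts for one transcript against one bank."""

    n_total: dict[str, int]
    n_recalled: dict[str, int]

    def pct(self, level: str) -> float:
        if self.n_total[level] == 0:
            return float("nan")
        return 100.0 * self.n_recalled[level] / self.n_total[level]


class PropositionBank:
    """A passage's propositions, roots, and synonym lexicon.

    The proposition reference graph must be acyclic; root ids flag the
    topic-bearing (main-idea) propositions. ``synonyms`` maps a lemma to
    the set of alternative lemmas accepted as full credit — an explicit
    per-bank lexicon standing in for the human scorers' synonym
    judgments.
    """

    def __init__(
        self,
        passage_id: str,
        propositions: list[Proposition],
        root_ids: list[str],
        synonyms: dict[str, set[str]] | None = None,
    ) -> None:
        if not propositions:
            raise ValueError("bank must contain at least one proposition")
        ids = {p.id for p in propositions}
        if len(ids) != len(propositions):
            raise ValueError("duplicate proposition ids")
        if not root_ids:
            raise ValueError("root_ids must be non-empty")
        if not set(root_ids) <= ids:
            raise ValueError(f"unknown root ids: {set(root_ids) - ids}")
        self.passage_id = passage_id
        self.propositions = list(propositions)
        self.root_ids = list(root_ids)
        self.synonyms = {k: set(v) for k, v in (synonyms or {}).items()}
        self._by_id = {p.id: p for p in self.propositions}
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        graph = {
            p.id: [a for a in p.args if a in self._by_id] for p in self.propositions
        }
        try:
            TopologicalSorter(graph).prepare()
        except CycleError as err:
            raise ValueError(f"proposition references form a cycle: {err.args[1]}") from err

    def __len__(self) -> int:
        return len(self.propositions)

    def prop(self, pid: str) -> Proposition:
        return self._by_id[pid]

    def is_prop_ref(self, arg: str) -> bool:
        return arg in self._by_id

    @classmethod
    def from_json(cls, path) -> "PropositionBank":
        """Load {passage_id, roots, synonyms, propositions:[{id, predicate, args}]}."""
        with open(path) as fh:
            obj = json.load(fh)
        props = [
            Proposition(p["id"], p["predicate"], tuple(p["args"]))
            for p in obj["propositions"]
        ]
        syns = {k: set(v) for k, v in obj.get("synonyms", {}).items()}
        return cls(obj["passage_id"], props, obj["roots"], syns)


def assign_levels(bank: PropositionBank) -> PropositionBank:
    """Assign each proposition one of the three hierarchy levels.

    Rule precedence: a root is main; a non-root referencing any main
    proposition as an argument is mid; everything else is detail.
    """
    roots = set(bank.root_ids)
    leveled = []
    for p in bank.propositions:
        if p.id in roots:
            level = "main"
        elif any(bank.is_prop_ref(a) and a in roots for a in p.args):
            level = "mid"
        else:
            level = "detail"
        leveled.append(Proposition(p.id, p.predicate, p.args, level))
    return PropositionBank(bank.passage_id, leveled, bank.root_ids, bank.synonyms)


def _lemma_matches(target: str, transcript_lemmas: set[str], synonyms: dict[str, set[str]]) -> bool:
    if target in transcript_lemmas:
        return True
    return bool(synonyms.get(target, set()) & transcript_lemmas)


def score_transcript(transcript: list[str], bank: PropositionBank) -> RecallScore:
    """Score a free-recall transcript against a level-assigned bank.

    Binary credit per proposition: the predicate and all atomic
    arguments must each match a transcript lemma directly or via the
    synonym lexicon.
    """
    if any(p.level is None for p in bank.propositions):
        raise ValueError("bank must be level-assigned first (assign_levels)")
    lemmas = {lemmatize(t) for t in transcript}
    lemmas.discard("")
    n_total = {lev: 0 for lev in LEVELS}
    n_recalled = {lev: 0 for lev in LEVELS}
    for p in bank.propositions:
        n_total[p.level] += 1
        required = [lemmatize(p.predicate)] + [
            lemmatize(a) for a in p.args if not bank.is_prop_ref(a)
        ]
        if all(_lemma_matches(r, lemmas, bank.synonyms) for r in required):
            n_recalled[p.level] += 1
    return RecallScore(n_total, n_recalled)


def aggregate_scores(
    scores: dict[tuple[str, str], RecallScore], plan
) -> pd.DataFrame:
    """Build the long cell table from per-(participant, passage) scores.

    One row per participant x passage x level with the design factors
    joined from the plan; proportion = n_recalled / n_total. Raises if
    any (participant, passage) in the plan lacks a score.
    """
    missing = [
        (r.participant, r.passage)
        for r in plan.table.itertuples()
        if (r.participant, r.passage) not in scores
    ]
    if missing:
        raise ValueError(f"missing scores for {len(missing)} cells, e.g. {missing[:5]}")
    rows = []
    for r in plan.table.itertuples():
        sc = scores[(r.participant, r.passage)]
        for lev in LEVELS:
            nt, nr = sc.n_total[lev], sc.n_recalled[lev]
            rows.append(
                (
                    r.participant,
                    r.passage,
                    r.format,
                    r.clarity,
                    r.predictability,
                    lev,
                    nt,
                    nr,
                    nr / nt if nt else float("nan"),
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "participant", "passage", "format", "clarity", "predictability",
            "level", "n_props", "n_recalled", "proportion",
        ],
    )
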