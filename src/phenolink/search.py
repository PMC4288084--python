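"""Token-level inverted index with tiered query-relaxation search.

Every non-suppressed English atom string is tokenized and indexed with
TF-IDF-style weights (idf(t) = ln(N / df(t)), N = number of indexed atoms).
A query is evaluated through five progressively more relaxed tiers:

1. exact phrase — all query tokens appear contiguously, in order;
2. proximity   — all tokens inside a sliding window of five atom tokens;
3. all-tokens  — every query token appears somewhere in the atom;
4. accumulate  — a strict majority of query tokens appears (unmatched
   query parts are simply ignored);
5. relaxed     — per-token fuzzy matching (Damerau-Levenshtein), Porter
   stemming, and prefix wildcard expansion of the final token.

A result surfaces once, at its best (lowest) tier; within a tier results
rank by the summed idf of their matched tokens, then label, then atom id.
Later tiers are not evaluated once ``max_results`` is filled by earlier
ones, which keeps the expensive vocabulary scan of tier 5 off the hot path.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

from ._text import damerau_levenshtein, porter_stem, tokenize
from .terminology import TerminologyGraph

#: Sliding-window width (in atom tokens) for the proximity tier.
PROXIMITY_WINDOW = 5

TIER_EXACT_PHRASE = 1
TIER_PROXIMITY = 2
TIER_ALL_TOKENS = 3
TIER_ACCUMULATE = 4
TIER_RELAXED = 5


@dataclass(frozen=True)
class IndexedAtom:
    atom_id: str
    cui: str
    label: str
    tokens: tuple[str, ...]


@dataclass
class SearchIndex:
    postings: dict[str, set[str]] = field(default_factory=dict)
    atoms: dict[str, IndexedAtom] = field(default_factory=dict)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def document_frequency(self, token: str) -> int:
        return len(self.postings.get(token, ()))

    def idf(self, token: str) -> float:
        df = self.document_frequency(token)
        if df == 0:
            return 0.0
        return math.log(self.n_atoms / df)


@dataclass(frozen=True)
class SearchResult:
    cui: str
    atom_id: str
    label: str
    tier: int
    score: float
    matched_tokens: frozenset[str]

    def sort_key(self) -> tuple:
        return (self.tier, -self.score, self.label, self.atom_id)


def build_search_index(graph: TerminologyGraph) -> SearchIndex:
    """Index every atom of a loaded graph (suppressed atoms are only present
    if the graph was loaded with ``include_suppressed``; they are skipped)."""
    index = SearchIndex()
    for atom in graph.atoms():
        if atom.suppressed:
            continue
        tokens = tuple(tokenize(atom.label))
        index.atoms[atom.atom_id] = IndexedAtom(
            atom_id=atom.atom_id, cui=atom.cui, label=atom.label, tokens=tokens
        )
        for token in set(tokens):
            index.postings.setdefault(token, set()).add(atom.atom_id)
    return index


# ---------------------------------------------------------------------------
# Tier predicates
# ---------------------------------------------------------------------------

def _contiguous_in_order(query: list[str], tokens: tuple[str, ...]) -> bool:
    n, m = len(tokens), len(query)
    return any(list(tokens[i : i + m]) == query for i in range(n - m + 1))


def _within_window(query: list[str], tokens: tuple[str, ...], window: int) -> bool:
    needed = set(query)
    n = len(tokens)
    if len(needed) > window:
        return False
    for i in range(max(1, n - window + 1)):
        if needed.issubset(tokens[i : i + window]):
            return True
    return False


def _fuzzy_threshold(token: str) -> int:
    return 2 if len(token) >= 5 else 1


def _relaxed_vocabulary_matches(
    index: SearchIndex, qtoken: str, is_last: bool
) -> set[str]:
    """Vocabulary tokens matching ``qtoken`` under fuzzy/stem/wildcard rules."""
    matches: set[str] = set()
    threshold = _fuzzy_threshold(qtoken)
    qstem = porter_stem(qtoken)
    for vtoken in index.postings:
        if vtoken == qtoken or porter_stem(vtoken) == qstem:
            matches.add(vtoken)
        elif is_last and vtoken.startswith(qtoken):
            matches.add(vtoken)
        elif damerau_levenshtein(qtoken, vtoken, cutoff=threshold) <= threshold:
            matches.add(vtoken)
    return matches


# ---------------------------------------------------------------------------
# Search
# ---------------------------------------------------------------------------

def tiered_search(index: SearchIndex, query: str, max_results: int = 20) -> list[SearchResult]:
    """Evaluate ``query`` through the five relaxation tiers.

    Returns at most ``max_results`` results sorted by
    (tier, -score, label, atom_id). A query that normalizes to zero tokens
    warns and returns an empty list.
    """
    qtokens = tokenize(query)
    if not qtokens:
        warnings.warn(f"query {query!r} normalizes to zero tokens", stacklevel=2)
        return []
    qset = set(qtokens)
    majority = len(qset) // 2 + 1

    results: dict[str, SearchResult] = {}

    # Tiers 1-4 share the exact-token candidate set.
    candidates: set[str] = set()
    for token in qset:
        candidates |= index.postings.get(token, set())
    for atom_id in candidates:
        atom = index.atoms[atom_id]
        matched = qset & set(atom.tokens)
        if matched == qset:
            if _contiguous_in_order(qtokens, atom.tokens):
                tier = TIER_EXACT_PHRASE
            elif _within_window(qtokens, atom.tokens, PROXIMITY_WINDOW):
                tier = TIER_PROXIMITY
            else:
                tier = TIER_ALL_TOKENS
        elif len(matched) >= majority:
            tier = TIER_ACCUMULATE
        else:
            continue  # may still surface at the relaxed tier
        score = sum(index.idf(t) for t in matched)
        results[atom_id] = SearchResult(
            cui=atom.cui,
            atom_id=atom_id,
            label=atom.label,
            tier=tier,
            score=score,
            matched_tokens=frozenset(matched),
        )

    filled = sum(1 for r in results.values() if r.tier <= TIER_ACCUMULATE)
    if filled < max_results:
        # Tier 5: per-query-token relaxed matching over the vocabulary.
        per_token: dict[str, set[str]] = {}
        for position, qtoken in enumerate(qtokens):
            per_token.setdefault(qtoken, set()).update(
                _relaxed_vocabulary_matches(index, qtoken, position == len(qtokens) - 1)
            )
        relaxed_candidates: set[str] = set()
        for vtokens in per_token.values():
            for vtoken in vtokens:
                relaxed_candidates |= index.postings[vtoken]
        for atom_id in relaxed_candidates - results.keys():
            atom = index.atoms[atom_id]
            token_set = set(atom.tokens)
            matched_vtokens: set[str] = set()
            for qtoken in qset:
                hits = per_token[qtoken] & token_set
                if hits:
                    matched_vtokens.add(max(hits, key=lambda t: (index.idf(t), t)))
            if not matched_vtokens:
                continue
            score = sum(index.idf(t) for t in matched_vtokens)
            results[atom_id] = SearchResult(
                cui=atom.cui,
                atom_id=atom_id,
                label=atom.label,
                tier=TIER_RELAXED,
                score=score,
                matched_tokens=frozenset(matched_vtokens),
            )

    ordered = sorted(results.values(), key=SearchResult.sort_key)
    return ordered[:max_results]
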