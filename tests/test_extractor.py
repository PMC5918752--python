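"""Tokenization, gazetteer matching, pattern rules and profiling."""

import random

import pytest
from hypothesis import given, strategies as st

from pecoscreen.characteristics import Characteristic
from pecoscreen.extractor import (
    CONFOUNDER_PATTERN,
    POPULATION_PATTERN,
    CharacteristicProfile,
    ExtractionConfig,
    ExtractionError,
    Field,
    detect_confounders,
    detect_population,
    extract_characteristics,
    match_lexicon,
    normalize_and_tokenize,
    stem,
)
from pecoscreen.lexicons import Lexicon, LexiconSet
from pecoscreen.reference_io import Reference

from conftest import make_lexicon

P = Characteristic.POPULATION
E = Characteristic.EXPOSURE
C = Characteristic.CONFOUNDER
O = Characteristic.OUTCOME


class TestTokenizer:
    def test_empty_text(self):
        assert normalize_and_tokenize("") == []

    def test_hyphen_splits(self):
        toks = normalize_and_tokenize("PFOA-exposed")
        assert [t.norm for t in toks] == ["pfoa", "exposed"]
        assert (toks[0].start, toks[0].end) == (0, 4)
        assert (toks[1].start, toks[1].end) == (5, 12)

    def test_slash_splits(self):
        assert [t.norm for t in normalize_and_tokenize("mg/kg")] == ["mg", "kg"]

    def test_comma_grouped_numeral_is_one_token(self):
        toks = normalize_and_tokenize("a cohort of 1,234 women")
        nums = [t for t in toks if t.is_number]
        assert len(nums) == 1 and nums[0].surface == "1,234"

    @given(st.text(max_size=300))
    def test_every_token_slices_back_to_its_surface(self, text):
        for tok in normalize_and_tokenize(text):
            assert text[tok.start : tok.end] == tok.surface
            if not tok.is_number:
                assert tok.surface.casefold() == tok.norm

    def test_offsets_strictly_increasing(self):
        words = ["alpha", "beta", "1,000", "gamma-delta"] * 50
        text = " ".join(words)
        toks = normalize_and_tokenize(text)
        assert all(a.end <= b.start for a, b in zip(toks, toks[1:]))


def naive_match_oracle(token_norms, phrase_seqs):
    """O(n*m) reference matcher: all matches, then leftmost-longest greedy."""
    all_matches = []
    for start in range(len(token_norms)):
        for seq in phrase_seqs:
            if tuple(token_norms[start : start + len(seq)]) == tuple(seq):
                all_matches.append((start, len(seq)))
    chosen = []
    pos = 0
    for start, length in sorted(all_matches, key=lambda m: (m[0], -m[1])):
        if start >= pos:
            chosen.append((start, length))
            pos = start + length
    return chosen


class TestMatchLexicon:
    def run(self, text, phrases, **cfg):
        tokens = normalize_and_tokenize(text)
        lex = make_lexicon(E, phrases)
        config = ExtractionConfig(**cfg) if cfg else ExtractionConfig()
        return match_lexicon(tokens, lex, config, text=text)

    def test_single_term(self):
        spans = self.run("serum PFOA levels", ["pfoa"])
        assert len(spans) == 1
        assert spans[0].surface == "PFOA"
        assert spans[0].characteristic is E

    def test_longest_match_wins(self):
        spans = self.run("low birth weight", ["birth weight", "weight"])
        assert [s.surface for s in spans] == ["birth weight"]

    def test_no_overlap_within_characteristic(self):
        spans = self.run("weight weight", ["weight weight", "weight"])
        assert [s.surface for s in spans] == ["weight weight"]

    def test_span_slices_back(self):
        text = "Cohort of PFOA-exposed workers"
        for s in self.run(text, ["pfoa"]):
            assert text[s.start : s.end] == s.surface

    def test_planted_phrases_all_recovered(self):
        rng = random.Random(5)
        phrases = [f"marker{c} probe{c}" for c in "abcdefghij"]
        filler = [f"filler{c}{d}" for c in "abcde" for d in "fghijklm"]
        words, planted = [], 0
        for _ in range(20):
            words.extend(rng.sample(filler, 3))
            words.append(rng.choice(phrases))
            planted += 1
            words.extend(rng.sample(filler, 2))
        spans = self.run(" ".join(words), phrases)
        assert len(spans) == planted

    def test_matches_identical_to_naive_oracle_on_random_texts(self):
        rng = random.Random(11)
        vocab = [f"w{c}" for c in "abcdefghijkl"]
        phrases = ["wa wb", "wb", "wc wd we", "we", "wf wa"]
        lex = make_lexicon(E, phrases)
        seqs = [tuple(p.split()) for p in phrases]
        for _ in range(50):
            text = " ".join(rng.choices(vocab, k=100))
            tokens = normalize_and_tokenize(text)
            spans = match_lexicon(tokens, lex, text=text)
            got = [
                (next(i for i, t in enumerate(tokens) if t.start == s.start),
                 len(s.phrase.split()))
                for s in spans
            ]
            assert got == naive_match_oracle([t.norm for t in tokens], seqs)

    def test_stemming_conflates_inflections(self):
        assert stem("exposures") == "exposure"
        assert stem("studies") == "study"
        assert not self.run("serum exposures measured", ["exposure"])
        spans = self.run(
            "serum exposures measured", ["exposure"], enable_stemming=True
        )
        assert len(spans) == 1


class TestPopulationPattern:
    def run(self, text, phrases=(), **cfg):
        tokens = normalize_and_tokenize(text)
        lex = make_lexicon(P, phrases) if phrases else Lexicon.empty(P)
        config = ExtractionConfig(**cfg) if cfg else ExtractionConfig()
        return detect_population(tokens, lex, config, text=text)

    def test_number_person_fires(self):
        spans = self.run("A total of 1,234 children were enrolled")
        assert any(s.phrase == POPULATION_PATTERN for s in spans)
        assert spans[0].surface == "1,234 children"

    def test_window_respected(self):
        text = "In 1998 the committee reviewed applications from women"
        assert self.run(text, max_pattern_window=5) == []

    def test_lexicon_route(self):
        spans = self.run("pregnant women were recruited", ["pregnant women"])
        assert [s.surface for s in spans] == ["pregnant women"]

    def test_out_of_dictionary_description_misses(self):
        # the classic dictionary-coverage failure: the population is
        # described as biological material, not as the people studied
        assert self.run("maternal cord blood samples", ["pregnant women"]) == []

    def test_pattern_can_be_disabled(self):
        assert self.run("1,234 children enrolled", population_pattern=False) == []


class TestConfounderPattern:
    def run(self, text, phrases=(), **cfg):
        tokens = normalize_and_tokenize(text)
        lex = make_lexicon(C, phrases) if phrases else Lexicon.empty(C)
        config = ExtractionConfig(**cfg) if cfg else ExtractionConfig()
        return detect_confounders(tokens, lex, config, text=text)

    @pytest.mark.parametrize(
        "text",
        [
            "estimates were adjusted for smoking and age",
            "we controlled for maternal age",
            "models adjusting for parity",
        ],
    )
    def test_adjustment_language_fires(self, text):
        spans = self.run(text)
        assert any(s.phrase == CONFOUNDER_PATTERN for s in spans)

    def test_no_adjustment_language_no_span(self):
        assert self.run("a descriptive account of the cohort") == []

    def test_adjust_without_for_does_not_fire(self):
        assert self.run("the adjusted estimates are shown") == []


def make_ref(abstract, title="A study", ref_id="r1"):
    return Reference(ref_id=ref_id, title=title, abstract=abstract)


class TestExtractCharacteristics:
    def test_hand_traced_pfoa_abstract(self, pfoa_lexicons):
        ref = make_ref(
            "PFOA exposure in pregnant women was associated with "
            "reduced birth weight"
        )
        profile = extract_characteristics(ref, pfoa_lexicons)
        assert profile.hits[P] and profile.hits[E] and profile.hits[O]
        assert not profile.hits[C]

    def test_out_of_dictionary_terms_miss(self, pfoa_lexicons):
        # exposure given as "PFC", population as "maternal cord blood":
        # both absent from the dictionaries, so both characteristics miss
        ref = make_ref(
            "PFC concentrations in maternal cord blood were measured"
        )
        profile = extract_characteristics(ref, pfoa_lexicons)
        assert not profile.hits[E]
        assert not profile.hits[P]

    def test_empty_lexicons_and_patterns_disabled_all_miss(self, empty_lexicons):
        ref = make_ref("Any abstract text with 1,234 children adjusted for age")
        config = ExtractionConfig(
            population_pattern=False, confounder_pattern=False
        )
        profile = extract_characteristics(ref, empty_lexicons, config)
        assert not any(profile.hits.values())

    def test_empty_abstract_is_an_error(self, pfoa_lexicons):
        with pytest.raises(ExtractionError, match="no abstract"):
            extract_characteristics(make_ref("  "), pfoa_lexicons)

    def test_title_matching_toggle(self, pfoa_lexicons):
        ref = make_ref("no relevant terms here", title="PFOA and fetal growth")
        with_title = extract_characteristics(ref, pfoa_lexicons)
        assert with_title.hits[E] and with_title.hits[O]
        without = extract_characteristics(
            ref, pfoa_lexicons, ExtractionConfig(match_title=False)
        )
        assert not without.hits[E] and not without.hits[O]

    def test_profile_invariant_hits_iff_spans(self, pfoa_lexicons):
        ref = make_ref("PFOA and birth weight in pregnant women")
        profile = extract_characteristics(ref, pfoa_lexicons)
        spanned = {s.characteristic for s in profile.spans}
        for c in Characteristic:
            assert profile.hits[c] == (c in spanned)

    def test_sentence_duplication_does_not_change_hits(self, pfoa_lexicons):
        sentence = "PFOA was measured in pregnant women."
        one = extract_characteristics(make_ref(sentence), pfoa_lexicons)
        three = extract_characteristics(
            make_ref(" ".join([sentence] * 3)), pfoa_lexicons
        )
        assert one.hits == three.hits

    @given(st.data())
    def test_enlarging_a_lexicon_never_turns_hit_to_miss(self, data):
        vocab = [f"word{c}" for c in "abcdefgh"]
        text = " ".join(
            data.draw(st.lists(st.sampled_from(vocab), min_size=5, max_size=40))
        )
        small = data.draw(
            st.sets(st.sampled_from(vocab), min_size=1, max_size=3)
        )
        extra = data.draw(st.sets(st.sampled_from(vocab), max_size=3))
        base = LexiconSet.all_empty().with_lexicon(make_lexicon(E, small))
        bigger = LexiconSet.all_empty().with_lexicon(
            make_lexicon(E, small | extra)
        )
        ref = make_ref(text)
        before = extract_characteristics(ref, base)
        after = extract_characteristics(ref, bigger)
        if before.hits[E]:
            assert after.hits[E]

    def test_inconsistent_profile_rejected(self):
        with pytest.raises(ValueError, match="inconsistent"):
            CharacteristicProfile(
                "r1",
                {c: False for c in Characteristic},
                spans=[
                    __import__("pecoscreen.extractor", fromlist=["TextSpan"])
                    .TextSpan("r1", Field.ABSTRACT, 0, 4, "pfoa", "pfoa", E)
                ],
            )
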