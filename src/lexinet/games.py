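"""The three interaction protocols: discrimination, guessing and naming games.

A *discrimination game* is a solo sub-game: the agent classifies all four
context stimuli and succeeds iff the topic lands in a category none of the
distractors occupy.  A *guessing game* is the full grounded protocol: the
speaker discriminates the topic, utters the word most strongly associated
with the topic's category, and the hearer points to the context stimulus
best matching the category it associates with that word.  The *naming game*
is the ungrounded variant over discrete stimuli, using the lexical layer
only.

Every game returns a :class:`GameOutcome` whose ``failure_branch`` records
which failure rule fired (exactly one per failed game).  Games run with
``learn=False`` evaluate the outcome without mutating either agent — used
for frozen communicative-success probes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .agents import (
    ASSOCIATION_STEP,
    INITIAL_ASSOCIATION,
    Agent,
    NamingAgent,
    WordFactory,
)
from .environments import GameContext

__all__ = [
    "GameOutcome",
    "discrimination_game",
    "guessing_game",
    "naming_game",
]


@dataclass(frozen=True)
class GameOutcome:
    success: bool
    failure_branch: str = "none"
    word_used: str | None = None
    speaker_category: int | None = None
    hearer_category: int | None = None

    def __post_init__(self) -> None:
        valid = {"none", "speaker-discrimination", "hearer-unknown-word",
                 "hearer-wrong-point"}
        if self.failure_branch not in valid:
            raise ValueError(f"unknown failure branch {self.failure_branch!r}")
        if self.success and self.failure_branch != "none":
            raise ValueError("successful games carry no failure branch")


def discrimination_game(
    agent: Agent,
    ctx: GameContext,
    learn: bool = True,
) -> tuple[bool, int | None]:
    """Solo categorization test on a 4-stimulus context.

    Success iff the topic's category differs from every distractor's
    category (an agent without categories always fails).  On failure with
    ``learn=True`` the agent applies the category-update rule to the topic
    and then forgets (unit-weight decay), as in the guessing-game failure
    branches.  Returns ``(success, topic_category_id)`` where the category
    id reflects any learning that occurred.
    """
    stimuli = np.asarray(ctx.stimuli, dtype=float)
    cats = agent.classify_many(stimuli)
    if cats is None:
        success, topic_cat = False, None
    else:
        topic_cat = cats[ctx.topic_index]
        success = all(cats[i] != topic_cat for i in ctx.distractor_indices())
    if not success and learn:
        topic_cat = agent.learn_topic(stimuli[ctx.topic_index]).id
        agent.decay_units()
    return success, topic_cat


def guessing_game(
    speaker: Agent,
    hearer: Agent,
    ctx: GameContext,
    words: WordFactory,
    learn: bool = True,
) -> GameOutcome:
    """One grounded guessing game between speaker and hearer.

    The failure branches are mutually exclusive and checked in protocol
    order: speaker discrimination failure (aborts before the hearer is
    involved; the hearer records nothing), hearer unknown word, hearer
    wrong point.  Both participants log the outcome in their trailing CS
    windows, except the hearer on the aborted branch.
    """
    stimuli = np.asarray(ctx.stimuli, dtype=float)
    topic = stimuli[ctx.topic_index]

    # 1. speaker plays the discrimination game (learning deferred to the
    #    failure branch so probe mode stays side-effect free)
    disc_ok, speaker_cat = discrimination_game(speaker, ctx, learn=False)
    if not disc_ok:
        if learn:
            speaker.learn_topic(topic)
            speaker.decay_units()
            speaker.record_outcome(False)
        return GameOutcome(False, "speaker-discrimination")

    # speaker utters the word naming C_s, minting one if the category is
    # unnamed (a fresh word enters the speaker's lexicon at strength 0.5)
    word = speaker.lexicon.strongest_word(speaker_cat)
    minted = word is None
    if minted:
        if not learn:
            # an unnamed category can never be guessed; count as the
            # unknown-word failure without minting any state
            return GameOutcome(False, "hearer-unknown-word",
                               speaker_category=speaker_cat)
        word = words.new_word()
        speaker.lexicon.set(speaker_cat, word, INITIAL_ASSOCIATION)

    # 2. hearer interprets the word
    hearer_cat = hearer.lexicon.strongest_category(word)
    if hearer_cat is None:
        if learn:
            _, learned_cat = discrimination_game(hearer, ctx, learn=True)
            hearer.lexicon.set(learned_cat, word, INITIAL_ASSOCIATION)
            hearer.decay_units()
            speaker.record_outcome(False)
            hearer.record_outcome(False)
        return GameOutcome(False, "hearer-unknown-word", word_used=word,
                           speaker_category=speaker_cat)

    responses = hearer.responses(stimuli)
    row = [c.id for c in hearer.categories].index(hearer_cat)
    pointed = int(np.argmax(responses[row]))

    if pointed == ctx.topic_index:
        if learn:
            speaker.lexicon.update(speaker_cat, word, ASSOCIATION_STEP)
            speaker.lexicon.inhibit_other_categories(word, keep=speaker_cat)
            hearer.lexicon.update(hearer_cat, word, ASSOCIATION_STEP)
            hearer.lexicon.inhibit_other_words(hearer_cat, keep=word)
            speaker.reinforce_category(speaker_cat, topic)
            hearer.reinforce_category(hearer_cat, topic)
            speaker.record_outcome(True)
            hearer.record_outcome(True)
        return GameOutcome(True, word_used=word,
                           speaker_category=speaker_cat,
                           hearer_category=hearer_cat)

    # 3. hearer pointed at a distractor
    if learn:
        speaker.lexicon.update(speaker_cat, word, -ASSOCIATION_STEP)
        hearer.lexicon.update(hearer_cat, word, -ASSOCIATION_STEP)
        hearer.learn_topic(topic)
        hearer.decay_units()
        speaker.record_outcome(False)
        hearer.record_outcome(False)
    return GameOutcome(False, "hearer-wrong-point", word_used=word,
                       speaker_category=speaker_cat,
                       hearer_category=hearer_cat)


def naming_game(
    speaker: NamingAgent,
    hearer: NamingAgent,
    ctx: GameContext,
    words: WordFactory,
    learn: bool = True,
) -> GameOutcome:
    """One ungrounded naming game over four distinct discrete stimuli."""
    stimuli = list(ctx.stimuli)
    if len(set(stimuli)) != 4:
        raise ValueError("naming game needs 4 distinct stimuli")
    topic = stimuli[ctx.topic_index]

    word = speaker.strongest_word(topic)
    minted = word is None
    if minted:
        if not learn:
            return GameOutcome(False, "hearer-unknown-word")
        word = words.new_word()
        speaker.set(topic, word, INITIAL_ASSOCIATION)

    if not hearer.knows_word(word):
        if learn:
            hearer.set(topic, word, INITIAL_ASSOCIATION)
            speaker.record_outcome(False)
            hearer.record_outcome(False)
        return GameOutcome(False, "hearer-unknown-word", word_used=word)

    pointed = hearer.point(word, stimuli)
    if pointed == ctx.topic_index:
        if learn:
            speaker.update(topic, word, ASSOCIATION_STEP)
            speaker.inhibit_other_stimuli(word, keep=topic)
            hearer.update(topic, word, ASSOCIATION_STEP)
            hearer.inhibit_other_words(topic, keep=word)
            speaker.record_outcome(True)
            hearer.record_outcome(True)
        return GameOutcome(True, word_used=word)

    if learn:
        speaker.update(topic, word, -ASSOCIATION_STEP)
        hearer.update(topic, word, -ASSOCIATION_STEP)
        speaker.record_outcome(False)
        hearer.record_outcome(False)
    return GameOutcome(False, "hearer-wrong-point", word_used=word)
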