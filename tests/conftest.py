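from datetime import datetime, timezone

import pytest

from tweetage.extract import load_rules
from tweetage.retrieval import RawTweet, load_patterns


def make_tweet(text, tweet_id="t1", user_id="u1", when="2018-06-01T12:00:00+00:00", retweeted=False):
    return RawTweet(
        tweet_id=tweet_id,
        user_id=user_id,
        created_at=datetime.fromisoformat(when),
        text=text,
        retweeted=retweeted,
    )


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def patterns():
    return load_patterns()


#: Worked examples: tweet surface forms exercising every arithmetic family,
#: with the exact age a reader derives by hand from the stated offsets.
GOLDEN_EXTRACTIONS = [
    # future offset in years: 21 - 2
    ("Two more years until my 21st birthday! Can't wait! #surprise", 19),
    # explicit present birthday
    ("It's my 18th birthday! And we have to go to school", 18),
    # bare possessive birthday (next birthday): 18 - 1
    ("excited for my 18th but also don't want to grow up", 17),
    # past period plus past age: 20 + 19
    ("I started having #depression 20 yrs ago at the age of 19.", 39),
    # two age mentions: max(28, 35)
    ("I started at 28 and I'm currently doing a PhD at 35.", 35),
    # at the age of N, present
    ("i feel like i'm going through a midlife crisis at the age of 21", 21),
    # repeated birthdays: 21 + (3 - 1)
    ("I've turned 21 three times now. I don't think I can turn it a 4th.", 23),
    # bare past turned
    ("I'm right there with you. Recently turned 47.", 47),
    # future offset in weeks with round-up: 18 - ceil(3/52)
    ("I was just reminded that I'm turning 18 in 3 weeks I feel old", 17),
    # since turning N, present
    ("I'm going out for the first time tonight since turning 21", 21),
    # explicit statement of present age
    ("It's my 21st birthday today. But who cares.…. ITS FINALLY AUGUST!!!!!", 21),
    # tomorrow I'll be N: 20 - 1
    ("It's crazy, tomorrow I'll be 20. I'm getting so OLD.", 19),
    # going to be N (next birthday): 21 - 1
    ("can't believe im going to be 21.…. i want to be a teenager again", 20),
]

#: The extractor's own documented near-miss behavior on possessive/turning
#: forms without a present-tense marker (predicted age = N - 1), plus the
#: spelled-out "two" case that must not fuse with the following digits.
NEAR_MISS_PREDICTIONS = [
    ("Blessed to see my 22nd birthday! I feel good to be alive.", 21),
    ("The most exciting part of turning 25 is that my insurance is dropping 20 bucks per month.", 24),
    ("Got to love Facebook for reminding me of my 21st bday cruise", 20),
    ("Who will be going to two 21st birthdays next week and doesn't have anything nothing to wear?! ME", 20),
]
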