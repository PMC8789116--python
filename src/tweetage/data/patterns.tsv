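# High-recall retrieval query patterns, v1.
# Columns: pattern_id	expression	description
# Applied (re.search) to retrieval-normalized text: lowercased, typographic
# punctuation mapped to ASCII, digit groups split by punctuation fused.
# Every numeric capture is constrained to the closed range 10-99 ([1-9]\d
# bounded on both sides), so "210" never yields "21".
p01	\b(?:i'?m|i\s+am|im)\s+(?:now\s+|almost\s+|finally\s+|officially\s+|only\s+)?([1-9]\d)\b	first-person present age
p02	\b([1-9]\d)\s*(?:years?|yrs?)\s*old\b	N years old
p03	\bmy\s+([1-9]\d)(?:st|nd|rd|th)\b	possessive ordinal (my 21st)
p04	\b([1-9]\d)(?:st|nd|rd|th)\s+(?:birthday|bday|b-?day)s?\b	ordinal birthday
p05	\bturn(?:ed|ing|s)?\s+([1-9]\d)\b	turned/turning/turns N
p06	\b(?:i'?ll|i\s+will|gonna|going\s+to|about\s+to|bouta)\s+be\s+([1-9]\d)\b	future be-age
p07	\bat\s+(?:the\s+age\s+of\s+)?([1-9]\d)\b	at (the age of) N
p08	\bsince\s+turning\s+([1-9]\d)\b	since turning N
p09	\bhappy\s+([1-9]\d)(?:st|nd|rd|th)\s+(?:birthday|bday)\s+to\s+me\b	birthday self-announcement
p10	\bthe\s+big\s+([1-9]\d)\b	the big N
p11	\b(?:\d+)\s+(?:more\s+)?(?:years?|yrs?|months?|weeks?|wks?|days?)\s+(?:until|till|til)\s+(?:my\s+)?([1-9]\d)	countdown to an age
p12	\b(?:\d+)\s+(?:years?|yrs?|months?|weeks?|days?)\s+(?:ago|back)\s+at\s+(?:the\s+age\s+of\s+)?([1-9]\d)\b	past period at past age
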