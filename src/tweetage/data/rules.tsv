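# Ordered age-extraction rule table, v1.
# Columns: order_index	rule_id	arithmetic	period_source	expression
# Rules are tried in ascending order_index on extraction-normalized text
# (lowercased, spelled numbers rewritten to digits, URLs/usernames removed,
# punctuation between digits fused). The first match wins. Named captures:
# n (age digits), n2 (second age), k (time-period digits), unit (time unit).
# More specific patterns carry lower order_index so that, e.g., the
# repeated-birthday rule fires before the bare turned-N rule.
10	until_my_nth	minus_period	n1	\b(?P<k>\d+)\s+(?:more\s+)?(?P<unit>years?|yrs?|months?|mos|weeks?|wks?|days?)\s+(?:left\s+)?(?:until|till|til|to)\s+(?:my\s+)?(?P<n>\d\d)(?:st|nd|rd|th)\b
20	until_im	minus_period	n1	\b(?P<k>\d+)\s+(?:more\s+)?(?P<unit>years?|yrs?|months?|mos|weeks?|wks?|days?)\s+(?:until|till|til)\s+(?:i'?m|i am|i turn)\s+(?P<n>\d\d)\b
30	turning_in	minus_period	n2	\bturn(?:ing|s|ed)?\s+(?P<n>\d\d)\s+in\s+(?P<k>\d+)\s+(?P<unit>years?|yrs?|months?|mos|weeks?|wks?|days?)\b
40	im_age_in	minus_period	n2	\b(?:i'?m|i am|im)\s+(?P<n>\d\d)\s+in\s+(?P<k>\d+)\s+(?P<unit>years?|yrs?|months?|mos|weeks?|wks?|days?)\b
50	birthday_in	minus_period	n2	\b(?:my\s+)?(?P<n>\d\d)(?:st|nd|rd|th)\s+(?:birthday|bday|b-?day)\s+(?:is\s+)?in\s+(?P<k>\d+)\s+(?P<unit>years?|yrs?|months?|mos|weeks?|wks?|days?)\b
60	turned_times	plus_repeats_minus_one	n2	\bturn(?:ed|ing)\s+(?P<n>\d\d)\s+(?P<k>\d+)\s+times\b
70	ago_at_age	plus_period	n1	\b(?P<k>\d+)\s+(?P<unit>years?|yrs?|months?|mos|weeks?|wks?|days?)\s+(?:ago|back)\s+at\s+(?:the\s+age\s+of\s+)?(?P<n>\d\d)\b
80	two_ages	max_of_two	none	\bat\s+(?P<n>\d\d)\b.*?\bat\s+(?:the\s+age\s+of\s+)?(?P<n2>\d\d)\b
90	its_my_nth	direct	none	\bit'?s\s+my\s+(?P<n>\d\d)(?:st|nd|rd|th)\b
100	happy_nth_to_me	direct	none	\bhappy\s+(?P<n>\d\d)(?:st|nd|rd|th)\s+(?:birthday|bday|b-?day)\s+to\s+me\b
110	my_nth_today	direct	none	\bmy\s+(?P<n>\d\d)(?:st|nd|rd|th)\s+(?:birthday|bday|b-?day)\s+(?:is\s+)?today\b
120	since_turning	direct	none	\bsince\s+turning\s+(?P<n>\d\d)\b
130	my_nth	minus_one	none	\bmy\s+(?P<n>\d\d)(?:st|nd|rd|th)\b
140	nth_birthday	minus_one	none	\b(?P<n>\d\d)(?:st|nd|rd|th)\s+(?:birthday|bday|b-?day)s?\b
150	will_be	minus_one	none	\b(?:i'?ll|i\s+will|gonna|going\s+to|about\s+to|bouta)\s+be\s+(?P<n>\d\d)\b
160	turning_bare	minus_one	none	\bturning\s+(?P<n>\d\d)\b
170	turned_bare	direct	none	\bturn(?:ed|s)?\s+(?P<n>\d\d)\b
180	years_old	direct	none	\b(?P<n>\d\d)\s+(?:years?|yrs?)\s*old\b
190	im_age	direct	none	\b(?:i'?m|i\s+am|im)\s+(?:now\s+)?(?P<n>\d\d)\b(?!\s*(?:st|nd|rd|th))
200	at_age	direct	none	\bat\s+(?:the\s+age\s+of\s+)?(?P<n>\d\d)\b
210	the_big	direct	none	\bthe\s+big\s+(?P<n>\d\d)\b
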