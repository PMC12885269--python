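The following text is a semi-structured clinical interview conducted by the virtual interviewer “Ellie” with interviewee “Participant” with varying depressive symptoms.

[Interview]

[INSERT_INTERVIEW]

[End of interview]

Based on the interview text, answer the following question.

Question: [INSERT_QUESTION]

Answer should be a score between 0 and 10, where 0 means “Not at all” and 10 means “Extremely”. Return only the score.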