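# Military-flavoured metaphors without exact lexicon tokens; these emulate
# metaphorical language in notes without tripping token-boundary matching.
Describes fighting a losing battle with his mood.
She has been soldiering on despite ongoing difficulties at home.
Feels under siege from intrusive thoughts during the night.
Describes his recovery as an uphill battle at times.
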