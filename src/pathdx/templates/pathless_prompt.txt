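Imagine you are a medical professional, and generate the top three direct and indirect diagnoses from the input note. {note}...
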