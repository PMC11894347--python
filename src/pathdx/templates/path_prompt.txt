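Imagine you are a medical professional equipped with a knowledge graph, and generate the top three direct and indirect diagnoses from the input note. {note}...These are knowledge paths: {paths}. Separate the diagnoses using semicolons, and explain your reasoning starting with <Reasoning>.
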