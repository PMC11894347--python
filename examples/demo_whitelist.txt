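causative_agent_of
associated_with
manifestation_of
due_to
finding_site_of
interprets
has_definitional_manifestation
temporally_follows
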