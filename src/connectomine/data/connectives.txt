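projects to
terminating in
receives input from
sends projections to
projects directly to
innervates
is connected with
sends axons to
receives afferents from
receives projections from
is reciprocally connected with
sends efferents to
provides input to
terminates in
gives rise to projections to
receives fibers from
sends fibers to
is innervated by
has reciprocal connections with
projects upon
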