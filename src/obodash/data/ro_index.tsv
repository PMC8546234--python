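# Curated subset of Relations Ontology properties: IRI <tab> label
http://purl.obolibrary.org/obo/BFO_0000050	part of
http://purl.obolibrary.org/obo/BFO_0000051	has part
http://purl.obolibrary.org/obo/BFO_0000066	occurs in
http://purl.obolibrary.org/obo/RO_0000052	characteristic of
http://purl.obolibrary.org/obo/RO_0000056	participates in
http://purl.obolibrary.org/obo/RO_0000057	has participant
http://purl.obolibrary.org/obo/RO_0000085	has function
http://purl.obolibrary.org/obo/RO_0000086	has quality
http://purl.obolibrary.org/obo/RO_0000087	has role
http://purl.obolibrary.org/obo/RO_0001025	located in
http://purl.obolibrary.org/obo/RO_0002131	overlaps
http://purl.obolibrary.org/obo/RO_0002160	only in taxon
http://purl.obolibrary.org/obo/RO_0002162	in taxon
http://purl.obolibrary.org/obo/RO_0002202	develops from
http://purl.obolibrary.org/obo/RO_0002211	regulates
http://purl.obolibrary.org/obo/RO_0002212	negatively regulates
http://purl.obolibrary.org/obo/RO_0002213	positively regulates
http://purl.obolibrary.org/obo/RO_0002215	capable of
http://purl.obolibrary.org/obo/RO_0002220	adjacent to
http://purl.obolibrary.org/obo/RO_0002233	has input
http://purl.obolibrary.org/obo/RO_0002234	has output
http://purl.obolibrary.org/obo/RO_0002333	enabled by
http://purl.obolibrary.org/obo/RO_0002350	member of
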