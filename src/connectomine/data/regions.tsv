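concept_id	name	source	is_preferred
R0001	substantia nigra pars compacta	toy	true
R0001	substantia nigra compact part	toy	false
R0002	substantia nigra pars reticulata	toy	true
R0003	ventral tegmental area	toy	true
R0004	dorsal raphe nucleus	toy	true
R0004	nucleus raphe dorsalis	toy	false
R0005	thalamic reticular nucleus	toy	true
R0006	caudate nucleus	toy	true
R0007	putamen	toy	true
R0008	globus pallidus	toy	true
R0009	subthalamic nucleus	toy	true
R0010	hippocampus	toy	true
R0011	dentate gyrus	toy	true
R0012	entorhinal cortex	toy	true
R0013	medial prefrontal cortex	toy	true
R0014	anterior cingulate cortex	toy	true
R0015	basolateral amygdala	toy	true
R0016	central amygdaloid nucleus	toy	true
R0017	nucleus accumbens	toy	true
R0017	accumbens nucleus	toy	false
R0018	olfactory bulb	toy	true
R0019	piriform cortex	toy	true
R0020	superior colliculus	toy	true
R0021	inferior colliculus	toy	true
R0022	periaqueductal gray	toy	true
R0023	locus coeruleus	toy	true
R0024	lateral habenula	toy	true
R0025	medial habenula	toy	true
R0026	paraventricular nucleus	toy	true
R0027	supraoptic nucleus	toy	true
R0028	arcuate nucleus	toy	true
R0029	lateral hypothalamic area	toy	true
R0030	suprachiasmatic nucleus	toy	true
R0031	ventral pallidum	toy	true
R0032	lateral septal nucleus	toy	true
R0033	medial septal nucleus	toy	true
R0034	nucleus basalis	toy	true
R0035	red nucleus	toy	true
R0036	inferior olive	toy	true
R0037	pontine nuclei	toy	true
R0038	cerebellar cortex	toy	true
R0039	fastigial nucleus	toy	true
R0040	interpositus nucleus	toy	true
R0041	cochlear nucleus	toy	true
R0042	nucleus of the solitary tract	toy	true
R0042	solitary tract nucleus	toy	false
R0043	spinal trigeminal nucleus	toy	true
R0044	ventral posteromedial nucleus	toy	true
R0045	lateral geniculate nucleus	toy	true
R0046	medial geniculate nucleus	toy	true
R0047	primary visual cortex	toy	true
R0048	primary motor cortex	toy	true
R0049	primary somatosensory cortex	toy	true
R0050	claustrum	toy	true
R0051	zona incerta	toy	true
R0052	parabrachial nucleus	toy	true
R0053	pedunculopontine nucleus	toy	true
R0054	lateral septum	toy	false
R0054	septal area	toy	true
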