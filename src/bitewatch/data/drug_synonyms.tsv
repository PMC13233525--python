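pattern	canonical_drug
blinatumomab	blinatumomab
blincyto	blinatumomab
amg 103	blinatumomab
mt103	blinatumomab
elranatamab	elranatamab
elrexfio	elranatamab
pf-06863135	elranatamab
epcoritamab	epcoritamab
epkinly	epcoritamab
gen3013	epcoritamab
glofitamab	glofitamab
columvi	glofitamab
rg6026	glofitamab
mosunetuzumab	mosunetuzumab
lunsumio	mosunetuzumab
rg7828	mosunetuzumab
talquetamab	talquetamab
talvey	talquetamab
jnj-64407564	talquetamab
tarlatamab	tarlatamab
imdelltra	tarlatamab
amg 757	tarlatamab
tebentafusp	tebentafusp
kimmtrak	tebentafusp
imcgp100	tebentafusp
teclistamab	teclistamab
tecvayli	teclistamab
jnj-64007957	teclistamab
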