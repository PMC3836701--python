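res,ALA,ARG,ASN,ASP,CYS,GLN,GLU,GLY,HIS,ILE,LEU,LYS,MET,PHE,PRO,SER,THR,TRP,TYR,VAL
ALA,1.230632,0.898102,0.944149,0.944149,1.274467,0.944149,0.944149,1.102443,0.958418,1.408504,1.360059,0.925453,1.236801,1.293728,1.038241,1.080613,1.086029,1.075223,1.053932,1.387534
ARG,0.898102,0.655425,0.689029,0.689029,0.930092,0.689029,0.689029,0.804550,0.699442,1.027911,0.992556,0.675385,0.902604,0.944149,0.757697,0.788619,0.792572,0.784686,0.769148,1.012607
ASN,0.944149,0.689029,0.724356,0.724356,0.977779,0.724356,0.724356,0.845801,0.735304,1.080613,1.043446,0.710013,0.948881,0.992556,0.796545,0.829053,0.833208,0.824918,0.808583,1.064525
ASP,0.944149,0.689029,0.724356,0.724356,0.977779,0.724356,0.724356,0.845801,0.735304,1.080613,1.043446,0.710013,0.948881,0.992556,0.796545,0.829053,0.833208,0.824918,0.808583,1.064525
CYS,1.274467,0.930092,0.977779,0.977779,1.319863,0.977779,0.977779,1.141711,0.992556,1.458675,1.408504,0.958418,1.280856,1.339811,1.075223,1.119104,1.124713,1.113522,1.091473,1.436958
GLN,0.944149,0.689029,0.724356,0.724356,0.977779,0.724356,0.724356,0.845801,0.735304,1.080613,1.043446,0.710013,0.948881,0.992556,0.796545,0.829053,0.833208,0.824918,0.808583,1.064525
GLU,0.944149,0.689029,0.724356,0.724356,0.977779,0.724356,0.724356,0.845801,0.735304,1.080613,1.043446,0.710013,0.948881,0.992556,0.796545,0.829053,0.833208,0.824918,0.808583,1.064525
GLY,1.102443,0.804550,0.845801,0.845801,1.141711,0.845801,0.845801,0.987606,0.858583,1.261786,1.218387,0.829053,1.107969,1.158966,0.930092,0.968050,0.972902,0.963222,0.944149,1.243001
HIS,0.958418,0.699442,0.735304,0.735304,0.992556,0.735304,0.735304,0.858583,0.746416,1.096944,1.059215,0.720744,0.963222,1.007557,0.808583,0.841582,0.845801,0.837385,0.820803,1.080613
ILE,1.408504,1.027911,1.080613,1.080613,1.458675,1.080613,1.080613,1.261786,1.096944,1.612085,1.556638,1.059215,1.415564,1.480720,1.188305,1.236801,1.243001,1.230632,1.206264,1.588084
LEU,1.360059,0.992556,1.043446,1.043446,1.408504,1.043446,1.043446,1.218387,1.059215,1.556638,1.503098,1.022784,1.366877,1.429791,1.147434,1.194262,1.200248,1.188305,1.164775,1.533463
LYS,0.925453,0.675385,0.710013,0.710013,0.958418,0.710013,0.710013,0.829053,0.720744,1.059215,1.022784,0.695954,0.930092,0.972902,0.780772,0.812636,0.816710,0.808583,0.792572,1.043446
MET,1.236801,0.902604,0.948881,0.948881,1.280856,0.948881,0.948881,1.107969,0.963222,1.415564,1.366877,0.930092,1.243001,1.300213,1.043446,1.086029,1.091473,1.080613,1.059215,1.394489
PHE,1.293728,0.944149,0.992556,0.992556,1.339811,0.992556,0.992556,1.158966,1.007557,1.480720,1.429791,0.972902,1.300213,1.360059,1.091473,1.136017,1.141711,1.130351,1.107969,1.458675
PRO,1.038241,0.757697,0.796545,0.796545,1.075223,0.796545,0.796545,0.930092,0.808583,1.188305,1.147434,0.780772,1.043446,1.091473,0.875928,0.911675,0.916245,0.907128,0.889166,1.170614
SER,1.080613,0.788619,0.829053,0.829053,1.119104,0.829053,0.829053,0.968050,0.841582,1.236801,1.194262,0.812636,1.086029,1.136017,0.911675,0.948881,0.953637,0.944149,0.925453,1.218387
THR,1.086029,0.792572,0.833208,0.833208,1.124713,0.833208,0.833208,0.972902,0.845801,1.243001,1.200248,0.816710,1.091473,1.141711,0.916245,0.953637,0.958418,0.948881,0.930092,1.224495
TRP,1.075223,0.784686,0.824918,0.824918,1.113522,0.824918,0.824918,0.963222,0.837385,1.230632,1.188305,0.808583,1.080613,1.130351,0.907128,0.944149,0.948881,0.939440,0.920837,1.212311
TYR,1.053932,0.769148,0.808583,0.808583,1.091473,0.808583,0.808583,0.944149,0.820803,1.206264,1.164775,0.792572,1.059215,1.107969,0.889166,0.925453,0.930092,0.920837,0.902604,1.188305
VAL,1.387534,1.012607,1.064525,1.064525,1.436958,1.064525,1.064525,1.243001,1.080613,1.588084,1.533463,1.043446,1.394489,1.458675,1.170614,1.218387,1.224495,1.212311,1.188305,1.564440
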