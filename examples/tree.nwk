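(((((((OTU6:0.8045814862,OTU20:0.7660104898):0.5736618252,OTU12:0.8514198015):0.9697570841,(((OTU19:0.3711183689,OTU17:0.4571027745):0.3011824182,OTU9:0.8105287148):0.9835274604,((OTU18:0.4937820636,OTU11:0.5629788204):0.4818272469,OTU36:0.2538212653):0.5507598846):0.2254540558):0.8251961156,(((OTU33:0.9552982794,(OTU40:0.753426833,(OTU22:0.3295670342,OTU5:0.7131438397):0.9687798016):0.9310743904):0.6374195829,OTU38:0.3999885754):0.084547214,((OTU1:0.4802289925,(OTU25:0.5579156336,(OTU37:0.3151718776,OTU29:0.6111570663):0.1097481494):0.837964784):0.6578253039,OTU4:0.0603691214):0.167397615):0.9889773194):0.3398542446,((OTU24:0.4115670927,OTU27:0.9888613789):0.1905803151,((OTU34:0.1580861348,OTU3:0.7467424672):0.6610932667,(OTU7:0.604399622,OTU15:0.5532082833):0.9814513908):0.9445349809):0.7739843284):0.5525883249,(((OTU23:0.2474303025,OTU31:0.0619853889):0.4295563863,(OTU16:0.6776523331,OTU26:0.3650610688):0.9901809156):0.3152871877,OTU2:0.8236970671):0.1250466619):0.2595816078,((OTU14:0.8752221556,(OTU35:0.1035607911,OTU21:0.2398031322):0.8090079817):0.5154122737,((OTU10:0.5766159474,OTU30:0.2678308685):0.8071436255,((OTU13:0.6464642133,OTU32:0.6025264284):0.5617823189,((OTU8:0.0089630749,OTU39:0.2962193448):0.4501537947,OTU28:0.7315604327):0.3580977446):0.4602851037):0.6713923929):0.5570316363);
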