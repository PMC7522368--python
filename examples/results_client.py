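"""A minimal remote client (End User) asking the results server for values.

Stimulus-presentation software requests a volume's results by sending its
0-based index as 4-digit zero-padded text; the reply is JSON. A volume not
yet processed answers {"foundResults": false} — the request never blocks —
so the client simply polls until the volume it needs arrives.
"""

from rtfmri.results_service import ResultsServer, ResultsStore, request_result

store = ResultsStore()
server = ResultsServer(store, port=0)  # ephemeral port for the demo
server.start()

print("request before volume 3 is processed:", request_result(3, port=server.port))
store.update(3, {"average": 1028.7})  # the engine does this after analysis
print("request after processing:           ", request_result(3, port=server.port))
server.stop()
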